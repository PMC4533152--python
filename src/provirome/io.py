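"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats only: FASTA (via Biopython), GFF3 with 1-based
inclusive coordinates, 12-column tabular similarity tables (BLAST
outfmt 6), and TSV tables for predictions, lineages and truth mappings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .curation import PredictionRecord
from .synthetic import (
    OUTFMT6_COLUMNS,
    PREDICTION_COLUMNS,
    GeneRecord,
    SyntheticWorld,
)
from .taxonomy import write_lineages


def write_fasta(path, seqs: Mapping[str, str], descriptions: Mapping[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _gff_line(seqid, source, ftype, start0, end0, strand, attrs: dict) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
    # GFF3 is 1-based inclusive; internal coordinates are 0-based half-open
    return f"{seqid}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr_str}"


def write_gff3(path, world: SyntheticWorld) -> None:
    """Gene calls for hosts and viral sequences, plus prophage regions."""
    lines = ["##gff-version 3"]
    for host in world.hosts:
        for vid, s, e in host.prophages:
            lines.append(
                _gff_line(host.genome_id, "provirome", "prophage_region", s, e, "+",
                          {"ID": f"{vid}_region", "virus_id": vid})
            )
        for g in host.genes:
            lines.append(_gene_line(g))
    for virus in world.viral_sequences:
        for g in virus.genes:
            lines.append(_gene_line(g))
    Path(path).write_text("\n".join(lines) + "\n")


def _gene_line(g: GeneRecord) -> str:
    attrs = {"ID": g.gene_id}
    if g.protein_id:
        attrs["protein_id"] = g.protein_id
    flags = [
        name
        for name, on in (
            ("hallmark", g.hallmark),
            ("terminase_LSU", g.terminase_lsu),
            ("parA", g.parA),
            ("parB", g.parB),
        )
        if on
    ]
    if flags:
        attrs["flags"] = ",".join(flags)
    attrs["category"] = g.category
    return _gff_line(g.sequence_id, "provirome", "CDS", g.start, g.end, g.strand, attrs)


def read_gff3_genes(path) -> pd.DataFrame:
    """Parse CDS lines back into a table (0-based half-open coordinates)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            flags = set(attrs.get("flags", "").split(",")) - {""}
            rows.append(
                {
                    "sequence_id": parts[0],
                    "gene_id": attrs.get("ID", ""),
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "protein_id": attrs.get("protein_id", ""),
                    "hallmark": "hallmark" in flags,
                    "terminase_lsu": "terminase_LSU" in flags,
                    "parA": "parA" in flags,
                    "parB": "parB" in flags,
                    "category": attrs.get("category", "other"),
                }
            )
    return pd.DataFrame(rows)


def write_similarity(path, table: pd.DataFrame) -> None:
    table[list(OUTFMT6_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def read_similarity(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)


def write_predictions(path, table: pd.DataFrame) -> None:
    table[list(PREDICTION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def predictions_to_records(table: pd.DataFrame) -> list[PredictionRecord]:
    """Prediction-table rows as records.

    The table dialect carries no explicit microbial-gene flag: a
    prophage is by definition embedded in a microbial contig, while
    curated non-prophage sequences are entirely viral, so the flag is
    derived from the prophage column.
    """
    records = []
    for row in table.itertuples(index=False):
        records.append(
            PredictionRecord(
                sequence_id=str(row.sequence_id),
                genome_id=str(row.genome_id),
                category=int(row.category),
                detection_tag=str(row.detection_tag),
                circular=bool(row.circular),
                prophage=bool(row.prophage),
                length_bp=int(row.length_bp),
                hallmark_count=int(row.hallmark_count),
                has_microbial_genes=bool(row.prophage),
                terl_count=int(row.terL_count),
                parA=bool(row.parA),
                parB=bool(row.parB),
                label=str(row.label),
            )
        )
    return records


def records_to_frame(records: Iterable[PredictionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "genome_id": r.genome_id,
                "category": r.category,
                "detection_tag": r.detection_tag,
                "circular": int(r.circular),
                "length_bp": r.length_bp,
                "prophage": int(r.prophage),
                "hallmark_count": r.hallmark_count,
                "terL_count": r.terl_count,
                "parA": int(r.parA),
                "parB": int(r.parB),
                "label": r.label,
            }
        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def write_world(world: SyntheticWorld, outdir) -> dict[str, Path]:
    """Serialise a synthetic world to a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hosts_fasta": outdir / "hosts.fna",
        "viruses_fasta": outdir / "viruses.fna",
        "proteins_fasta": outdir / "proteins.faa",
        "genes_gff": outdir / "genes.gff3",
        "similarity": outdir / "similarity.tsv",
        "predictions": outdir / "predictions.tsv",
        "gene_hits": outdir / "gene_hits.tsv",
        "host_lineages": outdir / "host_lineages.tsv",
        "virus_lineages": outdir / "virus_lineages.tsv",
        "truth_virus_host": outdir / "truth_virus_host.tsv",
        "truth_clusters": outdir / "truth_clusters.tsv",
        "truth_families": outdir / "truth_families.tsv",
    }
    write_fasta(paths["hosts_fasta"], {h.genome_id: h.sequence for h in world.hosts})
    write_fasta(paths["viruses_fasta"], world.virus_seqs())
    proteins = {}
    for virus in world.viral_sequences:
        for g in virus.genes:
            if g.protein_id:
                cds = Seq(virus.sequence[g.start : g.end])
                proteins[g.protein_id] = str(cds.translate())
    write_fasta(paths["proteins_fasta"], proteins)
    write_gff3(paths["genes_gff"], world)
    write_similarity(paths["similarity"], world.similarity)
    write_predictions(paths["predictions"], world.predictions)
    world.gene_hits.to_csv(paths["gene_hits"], sep="\t", index=False)
    write_lineages(paths["host_lineages"], world.host_lineages())
    write_lineages(
        paths["virus_lineages"],
        {v.virus_id: v.lineage for v in world.viral_sequences},
    )
    _write_mapping(paths["truth_virus_host"], world.truth.virus_host,
                   ("virus_id", "genome_id"))
    _write_mapping(paths["truth_clusters"], world.truth.virus_cluster,
                   ("virus_id", "true_cluster"))
    _write_mapping(paths["truth_families"], world.truth.protein_family,
                   ("protein_id", "true_family"))
    return paths


def _write_mapping(path, mapping: Mapping[str, str], header: tuple[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for key in sorted(mapping):
            fh.write(f"{key}\t{mapping[key]}\n")


def read_mapping(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_edge_list(path, graph) -> None:
    """Cytoscape-ready edge list: source<TAB>target<TAB>significance."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsignificance\n")
        for u, v, w in sorted(graph.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w:.4f}\n")


def write_matrix(path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="vc_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
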