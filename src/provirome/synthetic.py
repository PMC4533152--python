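"""Seeded synthetic world of microbial hosts and their viruses.

The generator emulates the statistical structure that every downstream
stage of the pipeline assumes, with known ground truth:

* a taxonomic hierarchy of hosts (two genera per family, one family per
  class/order) whose codon-usage signatures are drawn hierarchically —
  an order-level base distribution, perturbed per genus and again per
  species — so that composition distances recapitulate taxonomy;
* viral sequences whose codon distribution is an alpha-weighted mixture
  of the host species signature and a flat background, with per-virus
  adaptation strength varying below the configured ceiling (real viruses
  are not uniformly adapted to their hosts);
* viral gene repertoires drawn mostly from a per-genus protein-family
  pool, so gene-sharing clustering can recover the "genera";
* prophage insertion into host chromosomes vs extrachromosomal contigs
  (circular or linear);
* a similarity table with reciprocal within-family hits and none across
  families, clearing the score/e-value thresholds unambiguously;
* a prediction table containing decoys that each violate exactly one
  curation rule, plus PhiX-labelled control rows.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CODON_TO_AA
from .taxonomy import HOST_RANKS, VIRUS_RANKS, Lineage

#: Sense codons of the standard genetic code, the sampling alphabet.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

# Dirichlet concentrations of the hierarchical codon-bias model: the
# order-level base is strongly variable (conc 1 per codon), genera
# perturb their order base substantially and species their genus slightly.
ORDER_CONC = 1.0
GENUS_KAPPA = 200.0
SPECIES_KAPPA = 20000.0

#: Range of the per-virus adaptation multiplier u; the effective mixing
#: weight is alpha * u, so alpha is the ceiling of adaptation strength.
#: The wide range emulates the strong heterogeneity of real virus-host
#: amelioration (recently acquired viruses are poorly adapted).
ADAPTATION_JITTER = (0.4, 1.0)

# Observed ParA/ParB incidence used as generative rates: common among
# extrachromosomal viral sequences, rare elsewhere.
PARAB_RATE_EXTRACHROMOSOMAL = 0.13
PARAB_RATE_OTHER = 0.01

#: Viral families cycled over genera; Inoviridae-like genera get small
#: circular genomes detected by the non-Caudovirales score.
FAMILY_CYCLE = (
    ("Caudovirales", "Siphoviridae"),
    ("Caudovirales", "Myoviridae"),
    ("Caudovirales", "Podoviridae"),
    ("Tubulavirales", "Inoviridae"),
)

HOST_GENE_CODONS = 300
HOST_GENE_GAP_CODONS = 10

PREDICTION_COLUMNS = (
    "sequence_id", "genome_id", "category", "detection_tag", "circular",
    "length_bp", "prophage", "hallmark_count", "terL_count", "parA",
    "parB", "label",
)

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic world."""

    n_genera: int = 8
    hosts_per_genus: int = 4
    viruses_per_host: int = 2
    genome_length_bp: int = 200_000
    viral_length_range_bp: tuple[int, int] = (5_000, 40_000)
    alpha_host_mixing: float = 0.9
    family_pool_size: int = 40
    genes_per_virus: int = 20
    decoy_rate: float = 0.1
    prophage_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genera", "hosts_per_genus", "genome_length_bp",
                     "family_pool_size", "genes_per_virus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.viruses_per_host < 0:
            raise ValueError("viruses_per_host must be >= 0")
        lo, hi = self.viral_length_range_bp
        if lo < 1_000:
            raise ValueError("minimum viral length must be >= 1 kb")
        if lo > hi:
            raise ValueError("viral length range inverted")
        if hi > self.genome_length_bp:
            raise ValueError("viral length range exceeds genome_length_bp")
        for name in ("alpha_host_mixing", "decoy_rate", "prophage_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genes_per_virus * 9 > lo:
            raise ValueError("too many genes per virus for the minimum length")


@dataclass(frozen=True)
class GeneRecord:
    """One gene call; coordinates are 0-based half-open on its sequence."""

    gene_id: str
    sequence_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    family_id: str | None = None
    hallmark: bool = False
    terminase_lsu: bool = False
    parA: bool = False
    parB: bool = False
    category: str = "other"


@dataclass(eq=False)
class HostGenome:
    genome_id: str
    lineage: Lineage
    sequence: str
    genes: list[GeneRecord]
    prophages: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass(eq=False)
class ViralSequence:
    virus_id: str
    genome_id: str
    sequence: str
    circular: bool
    prophage_span: tuple[int, int] | None
    genes: list[GeneRecord]
    lineage: Lineage
    trna_count: int = 0
    adaptation: float = 1.0


@dataclass(eq=False)
class WorldTruth:
    virus_host: dict[str, str]
    virus_cluster: dict[str, str]
    protein_family: dict[str, str]
    virus_mode: dict[str, str]
    decoy_ids: set[str]


@dataclass(eq=False)
class SyntheticWorld:
    config: SimulationConfig
    hosts: list[HostGenome]
    viral_sequences: list[ViralSequence]
    similarity: pd.DataFrame
    predictions: pd.DataFrame
    gene_hits: pd.DataFrame
    truth: WorldTruth

    # -- convenience views used by the pipeline stages -----------------

    def host_by_id(self) -> dict[str, HostGenome]:
        return {h.genome_id: h for h in self.hosts}

    def virus_by_id(self) -> dict[str, ViralSequence]:
        return {v.virus_id: v for v in self.viral_sequences}

    def virus_seqs(self) -> dict[str, str]:
        return {v.virus_id: v.sequence for v in self.viral_sequences}

    def host_seqs(self, mask_prophages: bool = False) -> dict[str, str]:
        """Host chromosome sequences, optionally with prophages cut out."""
        out = {}
        for h in self.hosts:
            if mask_prophages and h.prophages:
                keep = []
                pos = 0
                for _, s, e in sorted(h.prophages, key=lambda t: t[1]):
                    keep.append(h.sequence[pos:s])
                    pos = e
                keep.append(h.sequence[pos:])
                out[h.genome_id] = "".join(keep)
            else:
                out[h.genome_id] = h.sequence
        return out

    def host_lineages(self) -> dict[str, Lineage]:
        return {h.genome_id: h.lineage for h in self.hosts}

    def host_cds(self) -> dict[str, list[str]]:
        """Host coding sequences (host genes only, prophages excluded)."""
        return {
            h.genome_id: [h.sequence[g.start : g.end] for g in h.genes]
            for h in self.hosts
        }

    def virus_cds(self) -> dict[str, list[str]]:
        return {
            v.virus_id: [v.sequence[g.start : g.end] for g in v.genes]
            for v in self.viral_sequences
        }

    def protein_to_virus(self) -> dict[str, str]:
        return {
            g.protein_id: v.virus_id
            for v in self.viral_sequences
            for g in v.genes
            if g.protein_id
        }

    def gene_counts(self) -> dict[str, int]:
        return {v.virus_id: len(v.genes) for v in self.viral_sequences}

    def virus_host_class(self) -> dict[str, str]:
        hosts = self.host_by_id()
        return {
            v.virus_id: hosts[v.genome_id].lineage.get("class")
            for v in self.viral_sequences
        }

    def sequence_metadata(self):
        from .network import SequenceMeta

        return {
            v.virus_id: SequenceMeta(
                circular=v.circular,
                complete=v.circular,
                length_bp=len(v.sequence),
                is_reference=False,
            )
            for v in self.viral_sequences
        }

    def genome_sequence_counts(self) -> dict[str, int]:
        counts = {h.genome_id: 1 for h in self.hosts}
        for v in self.viral_sequences:
            if v.prophage_span is None:
                counts[v.genome_id] = counts.get(v.genome_id, 0) + 1
        return counts


def _host_lineage(genus_idx: int, species_idx: int) -> Lineage:
    cls = genus_idx // 2
    return Lineage(
        HOST_RANKS,
        (
            "Bacteria",
            f"Phylum_{cls // 2}",
            f"Class_{cls}",
            f"Order_{cls}",
            f"Family_{cls}",
            f"Genus_{genus_idx}",
            f"Species_{genus_idx}_{species_idx}",
        ),
    )


def _virus_lineage(genus_idx: int) -> Lineage:
    order, family = FAMILY_CYCLE[genus_idx % len(FAMILY_CYCLE)]
    return Lineage(VIRUS_RANKS, (order, family, f"VGenus_{genus_idx}"))


def _sample_codon_sequence(rng: np.random.Generator, probs: np.ndarray,
                           n_codons: int) -> str:
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=probs)
    arr = np.array(SENSE_CODONS)
    return "".join(arr[idx])


def _viral_length(rng: np.random.Generator, cfg: SimulationConfig,
                  family: str) -> int:
    lo, hi = cfg.viral_length_range_bp
    if family == "Inoviridae":  # small circular ssDNA-like genomes
        upper = min(lo + 5_000, hi)
        length = int(rng.integers(lo, upper + 1))
    else:  # tailed-phage-like genomes, comfortably above the 10 kb rule
        lower = min(max(lo, 12_000), hi)
        length = int(rng.integers(lower, hi + 1))
    return length - length % 3


def generate_world(config: SimulationConfig) -> SyntheticWorld:
    """Build the full synthetic world; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_codons_alphabet = len(SENSE_CODONS)
    uniform = np.full(n_codons_alphabet, 1.0 / n_codons_alphabet)

    n_classes = math.ceil(cfg.n_genera / 2)
    order_base = rng.dirichlet(np.full(n_codons_alphabet, ORDER_CONC), size=n_classes)
    genus_probs = np.vstack(
        [rng.dirichlet(GENUS_KAPPA * order_base[g // 2]) for g in range(cfg.n_genera)]
    )

    hosts: list[HostGenome] = []
    species_probs: dict[str, np.ndarray] = {}
    for g in range(cfg.n_genera):
        for h in range(cfg.hosts_per_genus):
            genome_id = f"host_{g}_{h}"
            probs = rng.dirichlet(SPECIES_KAPPA * genus_probs[g])
            species_probs[genome_id] = probs
            n_cod = cfg.genome_length_bp // 3
            sequence = _sample_codon_sequence(rng, probs, n_cod)
            genes = []
            step = HOST_GENE_CODONS + HOST_GENE_GAP_CODONS
            i = 0
            while (i + 1) * step <= n_cod:
                start = i * step * 3
                end = start + HOST_GENE_CODONS * 3
                genes.append(
                    GeneRecord(
                        gene_id=f"{genome_id}_g{i:04d}",
                        sequence_id=genome_id,
                        start=start,
                        end=end,
                        strand="+",
                    )
                )
                i += 1
            hosts.append(
                HostGenome(genome_id, _host_lineage(g, h), sequence, genes)
            )

    # per-genus protein-family pools
    pools = {
        g: [f"fam_g{g}_{i:03d}" for i in range(cfg.family_pool_size)]
        for g in range(cfg.n_genera)
    }

    viruses: list[ViralSequence] = []
    truth = WorldTruth({}, {}, {}, {}, set())
    jitter_lo, jitter_hi = ADAPTATION_JITTER
    for g in range(cfg.n_genera):
        vlineage = _virus_lineage(g)
        family = vlineage.get("family")
        for h in range(cfg.hosts_per_genus):
            genome_id = f"host_{g}_{h}"
            for v in range(cfg.viruses_per_host):
                virus_id = f"virus_{g}_{h}_{v}"
                length = _viral_length(rng, cfg, family)
                u = float(rng.uniform(jitter_lo, jitter_hi))
                alpha_v = cfg.alpha_host_mixing * u
                probs = alpha_v * species_probs[genome_id] + (1 - alpha_v) * uniform
                sequence = _sample_codon_sequence(rng, probs, length // 3)
                is_prophage = bool(rng.random() < cfg.prophage_fraction)
                circular = False
                if not is_prophage:
                    p_circ = 0.9 if family == "Inoviridae" else 0.5
                    circular = bool(rng.random() < p_circ)
                genes = _viral_genes(rng, cfg, virus_id, length, vlineage, pools[g], truth)
                viruses.append(
                    ViralSequence(
                        virus_id=virus_id,
                        genome_id=genome_id,
                        sequence=sequence,
                        circular=circular,
                        prophage_span=None if not is_prophage else (-1, -1),
                        genes=genes,
                        lineage=vlineage,
                        trna_count=int(rng.poisson(1.0)),
                        adaptation=alpha_v,
                    )
                )
                truth.virus_host[virus_id] = genome_id
                truth.virus_cluster[virus_id] = f"VGenus_{g}"

    _insert_prophages(rng, hosts, viruses)
    _flag_markers(rng, viruses, truth)
    similarity = _similarity_table(rng, viruses)
    gene_hits = _gene_hit_table(rng, viruses)
    predictions = _prediction_table(rng, cfg, hosts, viruses, truth)
    return SyntheticWorld(cfg, hosts, viruses, similarity, predictions, gene_hits, truth)


def _viral_genes(rng, cfg, virus_id, length, vlineage, pool, truth):
    n_genes = cfg.genes_per_virus
    n_codons = length // 3
    bounds = np.linspace(0, n_codons, n_genes + 1).astype(int)
    # genus gene repertoires have core + accessory structure: a conserved
    # core present in every member, accessory genes sampled per virus
    n_family = max(1, round(0.9 * n_genes))
    n_core_set = min(max(1, round(0.6 * n_genes)), len(pool))
    core = list(pool[:n_core_set])
    accessory_pool = pool[n_core_set:]
    n_acc = min(max(0, n_family - n_core_set), len(accessory_pool))
    accessory = list(rng.choice(accessory_pool, size=n_acc, replace=False)) if n_acc else []
    core_fams = core + accessory
    categories = ("structure", "replication", "lysis", "integration", "other")
    genes = []
    for i in range(n_genes):
        start, end = int(bounds[i]) * 3, int(bounds[i + 1]) * 3
        if end - start < 9:
            continue
        protein_id = f"{virus_id}_p{i:02d}"
        family = core_fams[i] if i < len(core_fams) else None
        genes.append(
            GeneRecord(
                gene_id=f"{virus_id}_g{i:02d}",
                sequence_id=virus_id,
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
                protein_id=protein_id,
                family_id=family,
                hallmark=(i == 0 or (i == 1 and vlineage.get("order") == "Caudovirales")),
                terminase_lsu=(i == 1 and vlineage.get("order") == "Caudovirales"),
                category=categories[i % len(categories)],
            )
        )
        if family is not None:
            truth.protein_family[protein_id] = family
    return genes


def _insert_prophages(rng, hosts: list[HostGenome], viruses: list[ViralSequence]):
    by_host: dict[str, list[ViralSequence]] = {}
    for v in viruses:
        if v.prophage_span is not None:
            by_host.setdefault(v.genome_id, []).append(v)
    host_map = {h.genome_id: h for h in hosts}
    step = (HOST_GENE_CODONS + HOST_GENE_GAP_CODONS) * 3
    gap_offset = (HOST_GENE_CODONS + HOST_GENE_GAP_CODONS // 2) * 3
    for genome_id, pros in by_host.items():
        host = host_map[genome_id]
        n_gaps = max(len(host.genes) - 1, 1)
        sites = rng.choice(n_gaps, size=min(len(pros), n_gaps), replace=False)
        chosen = sorted(zip((int(s) for s in sites), pros), key=lambda t: t[0])
        segments: list[str] = []
        prev = 0
        offset = 0
        shifted_spans: list[tuple[object, int, int]] = []
        for site, virus in chosen:
            pos = site * step + gap_offset  # mid-gap, codon aligned
            segments.append(host.sequence[prev:pos])
            start = pos + offset
            span = (start, start + len(virus.sequence))
            segments.append(virus.sequence)
            shifted_spans.append((virus, span[0], span[1]))
            offset += len(virus.sequence)
            prev = pos
        segments.append(host.sequence[prev:])
        insert_points = [site * step + gap_offset for site, _ in chosen]
        lengths = [len(v.sequence) for _, v in chosen]
        genes = []
        for g in host.genes:
            shift = sum(
                L for p, L in zip(insert_points, lengths) if p <= g.start
            )
            if shift:
                g = GeneRecord(
                    **{**g.__dict__, "start": g.start + shift,
                       "end": g.end + shift}
                )
            genes.append(g)
        host.sequence = "".join(segments)
        host.genes = genes
        for virus, s, e in shifted_spans:
            virus.prophage_span = (s, e)
            virus.circular = False
            host.prophages.append((virus.virus_id, s, e))
        host.prophages.sort(key=lambda t: t[1])


def _flag_markers(rng, viruses: list[ViralSequence], truth: WorldTruth):
    for v in viruses:
        if v.prophage_span is not None:
            mode = "integrated"
        else:
            mode = "extrachromosomal"
        truth.virus_mode[v.virus_id] = mode
        looks_extra = v.prophage_span is None and (
            v.circular or len(v.sequence) > 30_000
        )
        rate = PARAB_RATE_EXTRACHROMOSOMAL if looks_extra else PARAB_RATE_OTHER
        if rng.random() < rate and len(v.genes) >= 2:
            v.genes[-2] = GeneRecord(**{**v.genes[-2].__dict__, "parA": True})
            v.genes[-1] = GeneRecord(**{**v.genes[-1].__dict__, "parB": True})


def _similarity_table(rng, viruses: list[ViralSequence]) -> pd.DataFrame:
    members: dict[str, list[tuple[str, int]]] = {}
    for v in viruses:
        for g in v.genes:
            if g.family_id is not None:
                members.setdefault(g.family_id, []).append(
                    (g.protein_id, (g.end - g.start) // 3)
                )
    rows = []
    for family in sorted(members):
        prots = members[family]
        if len(prots) < 2:
            continue
        for i, (p1, l1) in enumerate(prots):
            for p2, l2 in prots[i + 1 :]:
                score = float(rng.uniform(60, 300))
                pident = float(rng.uniform(40, 99))
                aln = min(l1, l2)
                for q, s, ql, sl in ((p1, p2, l1, l2), (p2, p1, l2, l1)):
                    rows.append(
                        (q, s, round(pident, 1), aln, int(aln * 0.2), 1,
                         1, aln, 1, aln, 1e-20, round(score, 1))
                    )
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def _gene_hit_table(rng, viruses: list[ViralSequence]) -> pd.DataFrame:
    """Per-gene best hits against reference profiles, for LCA affiliation."""
    lineages = sorted({str(v.lineage) for v in viruses})
    rows = []
    for v in viruses:
        for g in v.genes:
            if g.family_id is None:
                continue
            if rng.random() < 0.05 and len(lineages) > 1:
                wrong = [l for l in lineages if l != str(v.lineage)]
                lin = wrong[int(rng.integers(len(wrong)))]
                score = float(rng.uniform(60, 120))
            else:
                lin = str(v.lineage)
                score = float(rng.uniform(150, 300))
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "sequence_id": v.virus_id,
                    "target_id": f"profile_{g.family_id}",
                    "score": round(score, 1),
                    "lineage": lin,
                }
            )
    return pd.DataFrame(rows)


def _detection_tag(rng, family: str) -> str:
    if family == "Inoviridae":
        return "noncaudo"
    return str(rng.choice(["hallmark", "refseq", "vdb"], p=[0.7, 0.2, 0.1]))


def _prediction_table(rng, cfg, hosts, viruses, truth) -> pd.DataFrame:
    rows = []
    for v in viruses:
        hallmark_count = sum(g.hallmark for g in v.genes)
        terl = sum(g.terminase_lsu for g in v.genes)
        rows.append(
            {
                "sequence_id": v.virus_id,
                "genome_id": v.genome_id,
                "category": int(rng.integers(1, 3)),
                "detection_tag": _detection_tag(rng, v.lineage.get("family")),
                "circular": int(v.circular),
                "length_bp": len(v.sequence),
                "prophage": int(v.prophage_span is not None),
                "hallmark_count": hallmark_count,
                "terL_count": terl,
                "parA": int(any(g.parA for g in v.genes)),
                "parB": int(any(g.parB for g in v.genes)),
                "label": f"predicted virus in {v.genome_id}",
            }
        )
    n_decoys = round(cfg.decoy_rate * len(viruses))
    host_ids = [h.genome_id for h in hosts]
    for i in range(n_decoys):
        kind = i % 5
        genome_id = host_ids[int(rng.integers(len(host_ids)))]
        base = {
            "sequence_id": f"decoy_{i:04d}",
            "genome_id": genome_id,
            "category": 1,
            "detection_tag": "hallmark",
            "circular": 0,
            "length_bp": 15_000,
            "prophage": 0,
            "hallmark_count": 1,
            "terL_count": 0,
            "parA": 0,
            "parB": 0,
            "label": "decoy",
        }
        if kind == 0:
            base.update(label="Enterobacteria phage PhiX174", circular=1,
                        length_bp=5_386)
        elif kind == 1:
            base.update(category=3, hallmark_count=0)
        elif kind == 2:
            base.update(prophage=1, hallmark_count=0, category=2)
        elif kind == 3:
            base.update(length_bp=int(rng.integers(3_000, 10_000)))
        else:
            base.update(circular=1, length_bp=int(rng.integers(1_000, 3_000)))
        rows.append(base)
        truth.decoy_ids.add(base["sequence_id"])
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# genome fragmentation


@dataclass(frozen=True)
class Contig:
    """A fragment of a host genome with provenance kept as truth."""

    contig_id: str
    genome_id: str
    start: int
    end: int
    n_host_genes: int
    prophage_ids: tuple[str, ...]
    sequence: str | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def fully_viral(self) -> bool:
        return self.n_host_genes == 0 and bool(self.prophage_ids)


def split_genome(
    host: HostGenome, breakpoints: Sequence[int], with_sequences: bool = True
) -> list[Contig]:
    """Cut one host genome at the given positions (0-based, sorted)."""
    L = len(host.sequence)
    edges = [0] + sorted(int(b) for b in breakpoints) + [L]
    contigs = []
    for i in range(len(edges) - 1):
        s, e = edges[i], edges[i + 1]
        if s >= e:
            continue
        n_host = sum(1 for g in host.genes if g.start < e and g.end > s)
        pros = tuple(
            vid for vid, ps, pe in host.prophages if ps < e and pe > s
        )
        contigs.append(
            Contig(
                contig_id=f"{host.genome_id}_c{i:03d}",
                genome_id=host.genome_id,
                start=s,
                end=e,
                n_host_genes=n_host,
                prophage_ids=pros,
                sequence=host.sequence[s:e] if with_sequences else None,
            )
        )
    return contigs


def fragment_genomes(
    world: SyntheticWorld,
    target_contig_len_bp: int,
    seed: int = 0,
    with_sequences: bool = True,
    breakpoints: Mapping[str, Sequence[int]] | None = None,
) -> list[Contig]:
    """Fragment every host genome into draft-like contigs.

    Each genome is cut at ``ceil(L / target) - 1`` uniformly random
    breakpoints (none when the target is at least the genome length), or
    at explicitly supplied per-genome breakpoints.  Provenance — host
    gene count and overlapping prophages — is retained, so a prophage
    wholly contained in a contig with no host genes becomes a potential
    misclassification case for curation.
    """
    if target_contig_len_bp < 1_000:
        raise ValueError("target contig length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    for host in world.hosts:
        if breakpoints is not None and host.genome_id in breakpoints:
            bps = breakpoints[host.genome_id]
        else:
            L = len(host.sequence)
            n_contigs = math.ceil(L / target_contig_len_bp)
            if n_contigs <= 1:
                bps = []
            else:
                bps = sorted(
                    int(x) for x in rng.choice(
                        np.arange(1, L), size=n_contigs - 1, replace=False
                    )
                )
        contigs.extend(split_genome(host, bps, with_sequences=with_sequences))
    return contigs


# ---------------------------------------------------------------------------
# packaged curation fixture


def curation_fixture() -> pd.DataFrame:
    """Deterministic 25-row prediction table for filter validation.

    10 rows pass every curation rule (including the boundary cases: a
    6 kb linear non-Caudovirales detection and a 3 kb circular contig);
    the other 15 are decoys, three per rule, each violating exactly one
    rule.  Applying the curation filters must retain exactly the 10 and
    log 15 rejections with the correct first-violated rule.
    """
    rows = []

    def add(seq_id, category=1, tag="hallmark", circular=0, length=20_000,
            prophage=0, hallmark=1, label="ok"):
        rows.append(
            {
                "sequence_id": seq_id,
                "genome_id": "host_X",
                "category": category,
                "detection_tag": tag,
                "circular": circular,
                "length_bp": length,
                "prophage": prophage,
                "hallmark_count": hallmark,
                "terL_count": 0,
                "parA": 0,
                "parB": 0,
                "label": label,
            }
        )

    # --- 10 valid rows
    add("valid_01", length=35_000)
    add("valid_02", length=10_000)                       # linear boundary
    add("valid_03", tag="noncaudo", length=6_000)        # noncaudo exception
    add("valid_04", tag="noncaudo", length=5_000)        # noncaudo boundary
    add("valid_05", circular=1, length=3_000)            # circular boundary
    add("valid_06", circular=1, length=8_000)
    add("valid_07", prophage=1, length=42_000, category=2)
    add("valid_08", prophage=1, length=15_000, hallmark=2)
    add("valid_09", tag="refseq", length=12_000)
    add("valid_10", tag="vdb", circular=1, length=55_000)
    # --- 3 PhiX control rows
    add("phix_1", circular=1, length=5_386, label="Enterobacteria phage PhiX174")
    add("phix_2", circular=1, length=5_386, label="PhiX174 control")
    add("phix_3", length=11_000, label="phiX spike-in")
    # --- 3 category-3 rows
    add("cat3_1", category=3, length=25_000)
    add("cat3_2", category=3, circular=1, length=40_000)
    add("cat3_3", category=3, hallmark=0, length=18_000)
    # --- 3 defective prophages (no hallmark gene)
    add("nohall_1", prophage=1, hallmark=0, category=2, length=30_000)
    add("nohall_2", prophage=1, hallmark=0, category=2, length=12_000)
    add("nohall_3", prophage=1, hallmark=0, category=1, length=50_000)
    # --- 3 short linear rows (one under the noncaudo 5 kb floor)
    add("shortlin_1", length=9_999)
    add("shortlin_2", length=4_000)
    add("shortlin_3", tag="noncaudo", length=4_999)
    # --- 3 short circular rows
    add("shortcirc_1", circular=1, length=2_999)
    add("shortcirc_2", circular=1, length=1_200)
    add("shortcirc_3", circular=1, length=2_500)
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
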