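"""Co-infection detection across genome projects.

A genome project harbouring several distinct viral sequences is a
candidate co-infection.  Because a single large tailed phage
(Caudovirales) genome can mis-assemble into several contigs of one draft
genome, a safeguard applies when *all* of a genome's candidate sequences
are Caudovirales: the co-infection is only counted when at least two
copies of the terminase large subunit (terL) are present — terL is
single-copy in Caudovirales genomes and well conserved, so one copy
spread over several contigs points at one broken genome, not several
viruses.  Mixed-family candidates (e.g. an Inoviridae plus a
Caudovirales prophage) are counted regardless; gating those too is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import pandas as pd

from .taxonomy import UNASSIGNED

CAUDOVIRALES = "Caudovirales"

REQUIRED_COLUMNS = ("sequence_id", "genome_id", "order", "family", "terL_count")


@dataclass(frozen=True)
class CoinfectionRecord:
    genome_id: str
    n_viral_sequences: int
    terl_total: int
    counted: bool
    family_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.counted and self.n_viral_sequences < 2:
            raise ValueError("a counted co-infection needs >= 2 sequences")


def _family_label(family: str) -> str:
    return family if family and family != UNASSIGNED else "Unclassified"


def detect_coinfections(
    sequences: pd.DataFrame,
    terl_gate_mixed: bool = False,
) -> tuple[list[CoinfectionRecord], pd.DataFrame, pd.DataFrame]:
    """Tabulate per-genome viral counts and counted co-infection pairs.

    ``sequences`` needs columns ``sequence_id, genome_id, order, family,
    terL_count`` (order/family from the sequences' taxonomic
    affiliation).  Returns ``(records, histogram, pair_table)``:

    * one record per genome with >= 1 virus; genomes with >= 2 are
      candidates, counted unless the all-Caudovirales terL safeguard
      fires (or, with ``terl_gate_mixed=True``, whenever any
      Caudovirales member is present and terL copies total < 2);
    * a histogram of viruses-per-genome over all genomes with a virus;
    * unordered family-pair counts aggregated over counted genomes
      (a genome with n viruses contributes C(n, 2) pairs).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in sequences.columns]
    if missing:
        raise ValueError(f"sequence table lacks columns {missing}")
    bad = sequences["genome_id"].isna() | (sequences["genome_id"].astype(str) == "")
    if bad.any():
        culprit = sequences.loc[bad, "sequence_id"].iloc[0]
        raise ValueError(f"sequence {culprit!r} has no genome id")

    records: list[CoinfectionRecord] = []
    pair_counts: dict[tuple[str, str], int] = {}
    for genome_id, grp in sequences.groupby("genome_id", sort=True):
        n = len(grp)
        terl_total = int(grp["terL_count"].sum())
        counted = False
        pairs: tuple[tuple[str, str], ...] = ()
        if n >= 2:
            orders = list(grp["order"])
            all_caudo = all(o == CAUDOVIRALES for o in orders)
            any_caudo = any(o == CAUDOVIRALES for o in orders)
            if all_caudo or (terl_gate_mixed and any_caudo):
                counted = terl_total >= 2
            else:
                counted = True
            if counted:
                families = sorted(_family_label(f) for f in grp["family"])
                pairs = tuple(
                    tuple(sorted(p)) for p in combinations(families, 2)
                )
                for p in pairs:
                    pair_counts[p] = pair_counts.get(p, 0) + 1
        records.append(
            CoinfectionRecord(
                genome_id=str(genome_id),
                n_viral_sequences=n,
                terl_total=terl_total,
                counted=counted,
                family_pairs=pairs,
            )
        )

    hist = (
        pd.Series([r.n_viral_sequences for r in records], name="n_viruses")
        .value_counts()
        .sort_index()
        .rename_axis("n_viruses")
        .reset_index(name="n_genomes")
    )
    pair_rows = [
        {"family_1": a, "family_2": b, "n_pairs": c}
        for (a, b), c in sorted(pair_counts.items())
    ]
    pair_table = pd.DataFrame(pair_rows, columns=["family_1", "family_2", "n_pairs"])
    return records, hist, pair_table
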