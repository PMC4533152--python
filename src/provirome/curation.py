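"""Post-detection curation of viral predictions and replication-mode calls.

Automated viral-region detectors over-call: control-spike contamination
(PhiX), low-confidence predictions, defective prophages lacking any
virion (hallmark) gene, and short repeat-like contigs all need to be
removed before analysis.  The filters here run in a fixed order and log,
for every dropped row, the first rule it violated:

1. PhiX-labelled rows (Illumina sequencing control);
2. category-3 predictions (no hallmark gene and no gene enrichment);
3. prophage predictions with no hallmark gene (likely defective);
4. linear sequences shorter than 10 kb — 5 kb when detected with the
   non-Caudovirales score, since those viruses are often < 10 kb;
5. circular contigs shorter than 3 kb (likely short repeat regions);
6. sequences on an explicit exclusion list (manual curation is an input
   here, never recomputed).

Retained sequences are then classified by replication mode: integrated
prophage, extrachromosomal (circular or > 30 kb with no microbial gene),
or undetermined (short linear, could be either).  An exact conditional
rate test quantifies the enrichment of plasmid-partition markers
(ParA/ParB) among extrachromosomal sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

VALID_TAGS = frozenset({"hallmark", "refseq", "noncaudo", "vdb"})

MIN_LINEAR_BP = 10_000
MIN_LINEAR_NONCAUDO_BP = 5_000
MIN_CIRCULAR_BP = 3_000
EXTRACHROMOSOMAL_MIN_BP = 30_000

RULE_PHIX = "phix_control"
RULE_CATEGORY3 = "category_3"
RULE_PROPHAGE_NO_HALLMARK = "prophage_without_hallmark"
RULE_LINEAR_TOO_SHORT = "linear_too_short"
RULE_CIRCULAR_TOO_SHORT = "circular_too_short"
RULE_EXCLUDED = "excluded_by_list"

RULE_ORDER = (
    RULE_PHIX,
    RULE_CATEGORY3,
    RULE_PROPHAGE_NO_HALLMARK,
    RULE_LINEAR_TOO_SHORT,
    RULE_CIRCULAR_TOO_SHORT,
    RULE_EXCLUDED,
)


@dataclass(frozen=True)
class PredictionRecord:
    """One automated viral prediction, as read from a prediction table."""

    sequence_id: str
    genome_id: str
    category: int
    detection_tag: str
    circular: bool
    prophage: bool
    length_bp: int
    hallmark_count: int
    has_microbial_genes: bool
    terl_count: int = 0
    parA: bool = False
    parB: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.sequence_id}: length_bp must be > 0")
        if self.category not in (1, 2, 3):
            raise ValueError(f"{self.sequence_id}: category must be 1, 2 or 3")


INTEGRATED = "integrated"
EXTRACHROMOSOMAL = "extrachromosomal"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class CuratedViralSequence(PredictionRecord):
    replication_mode: str = UNDETERMINED

    def __post_init__(self) -> None:
        super().__post_init__()
        if (self.replication_mode == INTEGRATED) != self.prophage:
            raise ValueError(
                f"{self.sequence_id}: replication_mode inconsistent with prophage flag"
            )


@dataclass(frozen=True)
class Rejection:
    sequence_id: str
    rule: str


def _first_violation(
    rec: PredictionRecord, exclusions: frozenset[str]
) -> str | None:
    if "phix" in rec.label.lower():
        return RULE_PHIX
    if rec.category == 3:
        return RULE_CATEGORY3
    if rec.prophage and rec.hallmark_count == 0:
        return RULE_PROPHAGE_NO_HALLMARK
    if not rec.circular:
        floor = (
            MIN_LINEAR_NONCAUDO_BP
            if rec.detection_tag == "noncaudo"
            else MIN_LINEAR_BP
        )
        if rec.length_bp < floor:
            return RULE_LINEAR_TOO_SHORT
    if rec.circular and rec.length_bp < MIN_CIRCULAR_BP:
        return RULE_CIRCULAR_TOO_SHORT
    if rec.sequence_id in exclusions:
        return RULE_EXCLUDED
    return None


def apply_curation_filters(
    predictions: Iterable[PredictionRecord],
    exclusions: Iterable[str] | None = None,
) -> tuple[list[PredictionRecord], list[Rejection]]:
    """Apply the curation rules in order; keep survivors, log the rest.

    Returns ``(retained, rejections)``; each dropped row appears exactly
    once in the log, labelled with the first rule it violated.  Rows with
    an unknown detection tag raise.  The filter is idempotent on its own
    output (given the same exclusion list).
    """
    excl = frozenset(exclusions or ())
    predictions = list(predictions)
    for rec in predictions:
        if rec.detection_tag not in VALID_TAGS:
            raise ValueError(
                f"unknown detection tag {rec.detection_tag!r} on row {rec.sequence_id!r}"
            )
    retained: list[PredictionRecord] = []
    rejections: list[Rejection] = []
    for rec in predictions:
        rule = _first_violation(rec, excl)
        if rule is None:
            retained.append(rec)
        else:
            rejections.append(Rejection(rec.sequence_id, rule))
    return retained, rejections


def classify_replication_mode(record: PredictionRecord) -> CuratedViralSequence:
    """Classify a curated prediction as integrated / extrachromosomal / undetermined.

    Prophages are integrated.  Sequences assembled outside the host
    chromosome (no microbial gene) are extrachromosomal when circular or
    longer than 30 kb — short linear ones stay undetermined because an
    integrated prophage can assemble into a contig without host genes.
    A prophage with no microbial gene on its contig, or a non-prophage
    carrying microbial genes, is inconsistently annotated and rejected.
    """
    if record.prophage:
        if not record.has_microbial_genes:
            raise ValueError(
                f"{record.sequence_id}: prophage without microbial genes "
                "(inconsistent annotation)"
            )
        mode = INTEGRATED
    else:
        if record.has_microbial_genes:
            raise ValueError(
                f"{record.sequence_id}: non-prophage sequence with microbial "
                "genes (inconsistent annotation)"
            )
        if record.circular or record.length_bp > EXTRACHROMOSOMAL_MIN_BP:
            mode = EXTRACHROMOSOMAL
        else:
            mode = UNDETERMINED
    return CuratedViralSequence(
        **{f: getattr(record, f) for f in PredictionRecord.__dataclass_fields__},
        replication_mode=mode,
    )


def marker_enrichment_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided exact test for a higher per-sequence marker rate in group 1.

    The classical exact two-sample Poisson (rate-ratio) construction:
    conditional on the total count ``k1 + k2``, ``k1`` is binomial with
    success probability ``n1 / (n1 + n2)`` under equal rates.  Returns
    ``P(X >= k1)``.  With zero markers overall there is no signal and the
    p-value is 1.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("marker counts must satisfy 0 <= k <= n")
    if n1 + n2 <= 0:
        raise ValueError("empty groups")
    total = k1 + k2
    if total == 0:
        return 1.0
    p = n1 / (n1 + n2)
    return float(stats.binom.sf(k1 - 1, total, p))


def classify_genome_status(sequence_count: int) -> str:
    """'draft' for genome projects with more than 5 sequences, else 'complete'.

    The >5 cut-off avoids mislabelling complete genomes split over a few
    chromosomes/plasmids as drafts.
    """
    if sequence_count < 1:
        raise ValueError("a genome project has at least one sequence")
    return "draft" if sequence_count > 5 else "complete"


def prophage_misclassification_rates(
    world,
    thresholds: Sequence[int] = (10_000, 20_000, 30_000),
    n_replicates: int = 100,
    target_contig_len_bp: int = 20_000,
    seed: int = 0,
) -> dict[int, float]:
    """Fraction of integrated prophages that fragmentation would disguise.

    Host genomes are fragmented ``n_replicates`` times at random
    breakpoints; a prophage counts as misclassified at a size threshold
    when some contig made only of its (viral) sequence — no host gene —
    is at least that long, since such a contig would be read as an
    extrachromosomal virus.  Returns mean rate per threshold; by nesting
    of the contig sets the rate can only decrease as the threshold grows.
    """
    from .synthetic import fragment_genomes

    rng = np.random.default_rng(seed)
    n_prophages = sum(1 for v in world.viral_sequences if v.prophage_span is not None)
    if n_prophages == 0:
        raise ValueError("world has no integrated prophages")
    rates = {t: 0.0 for t in thresholds}
    for _ in range(n_replicates):
        contigs = fragment_genomes(
            world,
            target_contig_len_bp,
            seed=int(rng.integers(2**31 - 1)),
            with_sequences=False,
        )
        best: dict[str, int] = {}
        for ctg in contigs:
            if ctg.n_host_genes > 0:
                continue
            for vid in ctg.prophage_ids:
                best[vid] = max(best.get(vid, 0), ctg.length_bp)
        for t in thresholds:
            hit = sum(1 for length in best.values() if length >= t)
            rates[t] += hit / n_prophages
    return {t: r / n_replicates for t, r in rates.items()}
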