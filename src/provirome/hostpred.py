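"""Alignment-free host prediction from tetranucleotide frequencies.

A virus's host is predicted as the microbial genome with the smallest
mean-absolute-error distance between tetranucleotide frequency (TNF)
vectors.  Prediction confidence tracks the distance itself, so results
are reported in three distance bins (d < 4e-4, 4e-4 <= d < 1e-3,
d >= 1e-3) and accuracy is scored at the order, family and genus rank of
the predicted genome's taxonomy.  Two exclusion modes probe how the
method degrades when close references are missing: leave out the host
species, or the whole host genus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import KmerVector, kmer_frequencies, mae_distance
from .taxonomy import Lineage

#: Distance bin edges, closed on the left and open on the right.
BIN_EDGES = (4e-4, 1e-3)

BIN_LABELS = ("d<4e-04", "4e-04<=d<1e-03", "d>=1e-03")

EXCLUSION_MODES = ("none", "host_species", "host_genus")

RANKS_SCORED = ("order", "family", "genus")


def assign_bin(d: float) -> str:
    if d < BIN_EDGES[0]:
        return BIN_LABELS[0]
    if d < BIN_EDGES[1]:
        return BIN_LABELS[1]
    return BIN_LABELS[2]


@dataclass(frozen=True)
class HostPrediction:
    virus_id: str
    predicted_genome: str
    distance: float
    bin: str
    exclusion: str
    correct_order: bool
    correct_family: bool
    correct_genus: bool

    def __post_init__(self) -> None:
        if self.bin != assign_bin(self.distance):
            raise ValueError("bin inconsistent with distance")


def host_tnf_library(
    host_seqs: Mapping[str, str], k: int = 4
) -> dict[str, KmerVector]:
    """TNF vector per host genome (concatenated contigs).

    Callers should normally pass chromosome sequences with known
    prophage regions already masked, so a virus is not compared against
    a genome that literally contains it.
    """
    return {gid: kmer_frequencies(seq, k) for gid, seq in host_seqs.items()}


def predict_host(
    virus_tnf: KmerVector,
    library: Mapping[str, KmerVector],
    host_lineages: Mapping[str, Lineage],
    true_host: str,
    exclusion: str = "none",
    virus_id: str = "",
) -> HostPrediction:
    """Nearest-genome host prediction under an exclusion mode.

    ``exclusion='host_species'`` removes every genome of the true host's
    species from the library; ``'host_genus'`` removes the whole genus.
    The prediction is the eligible genome with minimal TNF MAE distance
    (ties broken by lexicographic genome id); correctness compares the
    predicted genome's lineage with the true host's at each rank.
    """
    if exclusion not in EXCLUSION_MODES:
        raise ValueError(f"unknown exclusion mode {exclusion!r}")
    truth = host_lineages[true_host]
    eligible = []
    for gid in sorted(library):
        lin = host_lineages[gid]
        if exclusion == "host_species" and lin.get("species") == truth.get("species"):
            continue
        if exclusion == "host_genus" and lin.get("genus") == truth.get("genus"):
            continue
        eligible.append(gid)
    if not eligible:
        raise ValueError(f"exclusion mode {exclusion!r} empties the host library")
    best_id, best_d = None, np.inf
    for gid in eligible:  # sorted, so ties keep the lexicographically first
        d = mae_distance(virus_tnf, library[gid])
        if d < best_d:
            best_id, best_d = gid, d
    pred_lin = host_lineages[best_id]
    return HostPrediction(
        virus_id=virus_id,
        predicted_genome=best_id,
        distance=float(best_d),
        bin=assign_bin(float(best_d)),
        exclusion=exclusion,
        correct_order=pred_lin.get("order") == truth.get("order"),
        correct_family=pred_lin.get("family") == truth.get("family"),
        correct_genus=pred_lin.get("genus") == truth.get("genus"),
    )


def evaluate_predictions(predictions: Sequence[HostPrediction]) -> pd.DataFrame:
    """Accuracy per exclusion mode, distance bin and taxonomic rank.

    Returns a long-format table with columns ``exclusion, bin, rank, n,
    n_correct, ratio_pct`` (one block per exclusion mode, rows in
    distance-bin order — the layout of a host-prediction accuracy
    table).  Empty cells get n = 0 and an undefined ratio.
    """
    rows = []
    preds = list(predictions)
    modes = sorted({p.exclusion for p in preds}, key=EXCLUSION_MODES.index)
    for mode in modes:
        in_mode = [p for p in preds if p.exclusion == mode]
        for bin_label in BIN_LABELS:
            in_bin = [p for p in in_mode if p.bin == bin_label]
            for rank in RANKS_SCORED:
                correct = sum(getattr(p, f"correct_{rank}") for p in in_bin)
                n = len(in_bin)
                rows.append(
                    {
                        "exclusion": mode,
                        "bin": bin_label,
                        "rank": rank,
                        "n": n,
                        "n_correct": correct,
                        "ratio_pct": 100.0 * correct / n if n else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def accuracy_at_rank(
    predictions: Sequence[HostPrediction], rank: str, exclusion: str = "none"
) -> float:
    """Overall accuracy (fraction) at one rank for one exclusion mode."""
    preds = [p for p in predictions if p.exclusion == exclusion]
    if not preds:
        raise ValueError(f"no predictions for exclusion mode {exclusion!r}")
    return sum(getattr(p, f"correct_{rank}") for p in preds) / len(preds)


def host_prediction_experiment(
    virus_seqs: Mapping[str, str],
    host_seqs: Mapping[str, str],
    virus_host: Mapping[str, str],
    host_lineages: Mapping[str, Lineage],
    exclusions: Sequence[str] = EXCLUSION_MODES,
    k: int = 4,
) -> list[HostPrediction]:
    """Predict every virus's host under each exclusion mode."""
    library = host_tnf_library(host_seqs, k=k)
    out = []
    for vid in sorted(virus_seqs):
        tnf = kmer_frequencies(virus_seqs[vid], k)
        for mode in exclusions:
            out.append(
                predict_host(
                    tnf, library, host_lineages, virus_host[vid],
                    exclusion=mode, virus_id=vid,
                )
            )
    return out
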