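"""Genome-composition metrics and virus-host adaptation experiments.

A virus replicating in a host cell is exposed to the host's replication
and translation machinery, which leaves a measurable imprint: viral
genomes tend to resemble their host in oligonucleotide composition and in
codon usage.  This module provides the primitives used to quantify that
imprint —

* k-mer relative-frequency vectors (k = 1..4) and the mean-absolute-error
  (MAE) distance between them,
* codon usage tables with relative adaptiveness ``w`` and the codon
  adaptation index (CAI, geometric mean of ``w`` over a gene's codons),
* the two-sample Kolmogorov-Smirnov statistic ``D`` comparing the
  distribution of virus-to-host distances with virus-to-non-host
  distances,

and the two experiments built on them: the per-category adaptation report
(host vs 10 random same-genus / same-family / different-order genomes)
and the fragment-size subsampling experiment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .taxonomy import Lineage

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

#: Floor applied to the relative adaptiveness of codons absent from the
#: reference gene set, so CAI stays finite and positive.
W_FLOOR = 1e-3

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

#: codon -> amino acid for the standard genetic code.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

#: amino acid -> tuple of synonymous codons.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_SINGLE_CODON = frozenset(
    codons[0] for codons in SYNONYMOUS_FAMILIES.values() if len(codons) == 1
)

# lexicographic codon list and index helpers for vectorised counting
_ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)
_CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(_ALL_CODONS)}
_CAI_EXCLUDED = np.array(
    [(c in STOP_CODONS or c in _SINGLE_CODON) for c in _ALL_CODONS]
)


def _codon_indices(cds: str) -> np.ndarray:
    """Codon indices of an in-frame CDS; codons with non-ACGT get -1."""
    codes = _codes(cds)
    n = (len(codes) // 3) * 3
    tri = codes[:n].reshape(-1, 3)
    idx = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    idx[(tri < 0).any(axis=1)] = -1
    return idx


@dataclass(frozen=True)
class KmerVector:
    """Relative frequencies of the 4**k k-mers (lexicographic A<C<G<T)."""

    k: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 8:
            raise ValueError("k must be in 1..8")
        if self.freqs.shape != (4**self.k,):
            raise ValueError("frequency vector has wrong length for k")


def _codes(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def kmer_counts(sequence: str, k: int) -> np.ndarray:
    """Counts of overlapping k-mers; windows containing non-ACGT are skipped."""
    if len(sequence) < k:
        raise ValueError("sequence shorter than k")
    codes = _codes(sequence)
    n_win = len(codes) - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for off in range(k):
        col = codes[off : off + n_win]
        valid &= col >= 0
        idx = idx * 4 + col
    idx = idx[valid]
    if idx.size == 0:
        raise ValueError("no valid k-mer window (non-ACGT characters)")
    return np.bincount(idx, minlength=4**k)


def _revcomp_permutation(k: int) -> np.ndarray:
    perm = np.empty(4**k, dtype=np.int64)
    for i, mer in enumerate(itertools.product(range(4), repeat=k)):
        rc = 0
        for b in reversed(mer):  # complement A<->T (0<->3), C<->G (1<->2)
            rc = rc * 4 + (3 - b)
        perm[i] = rc
    return perm


def kmer_frequencies(sequence: str, k: int, canonical: bool = False) -> KmerVector:
    """Relative k-mer frequencies of one strand of ``sequence``.

    With ``canonical=True`` each k-mer is pooled with its reverse
    complement (frequencies averaged over the two strands).
    """
    counts = kmer_counts(sequence, k).astype(float)
    if canonical:
        counts = (counts + counts[_revcomp_permutation(k)]) / 2.0
    return KmerVector(k, counts / counts.sum())


def mae_distance(v1: KmerVector, v2: KmerVector) -> float:
    """Mean absolute difference between two same-k frequency vectors."""
    if v1.k != v2.k:
        raise ValueError(f"k mismatch: {v1.k} vs {v2.k}")
    return float(np.mean(np.abs(v1.freqs - v2.freqs)))


@dataclass(frozen=True)
class CodonUsageTable:
    """Within-family codon frequencies and relative adaptiveness.

    ``frequency[c]`` is the frequency of codon ``c`` within its synonymous
    family; ``relative_adaptiveness[c]`` (the CAI ``w``) is that frequency
    divided by the largest frequency in the family, so every family has
    max ``w`` = 1.  Codons never observed in an otherwise observed family
    get ``w`` = :data:`W_FLOOR`; families with no observation at all are
    uninformative and get ``w`` = 1 for each member.
    """

    frequency: Mapping[str, float]
    relative_adaptiveness: Mapping[str, float]


def codon_usage_table(cds_set: Iterable[str] | Mapping[str, str]) -> CodonUsageTable:
    """Build a codon usage table from a set of coding sequences.

    Accepts an iterable of CDS strings or a mapping name -> CDS.  Every
    CDS must have length divisible by 3; stop codons are counted but take
    no part in ``w`` (they form no synonymous family here).
    """
    if isinstance(cds_set, Mapping):
        items = list(cds_set.items())
    else:
        items = [(f"cds_{i}", s) for i, s in enumerate(cds_set)]
    all_counts = np.zeros(64, dtype=np.int64)
    for name, cds in items:
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {name!r} has length not divisible by 3")
        idx = _codon_indices(cds)
        idx = idx[idx >= 0]
        all_counts += np.bincount(idx, minlength=64)
    counts = {c: int(all_counts[_CODON_INDEX[c]]) for c in CODON_TO_AA}
    freq: dict[str, float] = {}
    w: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        total = sum(counts[c] for c in codons)
        if total == 0:
            for c in codons:
                freq[c] = 0.0
                w[c] = 1.0
            continue
        fam_freqs = {c: counts[c] / total for c in codons}
        fmax = max(fam_freqs.values())
        for c in codons:
            freq[c] = fam_freqs[c]
            w[c] = fam_freqs[c] / fmax if fam_freqs[c] > 0 else W_FLOOR
    return CodonUsageTable(freq, w)


def cai(cds: str, table: CodonUsageTable) -> float:
    """Codon adaptation index of one gene against a reference usage table.

    Geometric mean of ``w`` over the gene's codons; stop codons and
    single-codon families (ATG, TGG) are excluded because their ``w`` is 1
    by construction and carries no signal.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    log_w = _table_log_w(table)
    idx = _codon_indices(cds)
    idx = idx[idx >= 0]  # ambiguous bases carry no information
    logs = log_w[idx]
    logs = logs[~np.isnan(logs)]
    if logs.size == 0:
        raise ValueError("gene contains only excluded codons")
    return float(np.exp(np.mean(logs)))


def _table_log_w(table: CodonUsageTable) -> np.ndarray:
    """log w per codon index; NaN marks codons excluded from CAI."""
    cached = getattr(table, "_log_w_cache", None)
    if cached is not None:
        return cached
    log_w = np.full(64, np.nan)
    for codon, w in table.relative_adaptiveness.items():
        if not _CAI_EXCLUDED[_CODON_INDEX[codon]]:
            log_w[_CODON_INDEX[codon]] = np.log(w)
    object.__setattr__(table, "_log_w_cache", log_w)
    return log_w


def sequence_cai(genes: Iterable[str], table: CodonUsageTable) -> float:
    """Mean CAI over a sequence's genes."""
    values = [cai(g, table) for g in genes]
    if not values:
        raise ValueError("no genes supplied")
    return float(np.mean(values))


def ks_statistic(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov distance sup|ECDF1 - ECDF2|."""
    xs = np.sort(np.asarray(sample1, dtype=float))
    ys = np.sort(np.asarray(sample2, dtype=float))
    if xs.size == 0 or ys.size == 0:
        raise ValueError("K-S statistic requires two non-empty samples")
    grid = np.concatenate([xs, ys])
    cdf1 = np.searchsorted(xs, grid, side="right") / xs.size
    cdf2 = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.max(np.abs(cdf1 - cdf2)))


# ---------------------------------------------------------------------------
# adaptation experiments

#: metric name -> k for the k-mer metrics.
KMER_METRICS = {"k1": 1, "k2": 2, "k3": 3, "k4": 4}

CATEGORIES = ("same_genus", "same_family", "different_order")


def _category_candidates(
    host_id: str, host_lineages: Mapping[str, Lineage]
) -> dict[str, list[str]]:
    lin = host_lineages[host_id]
    genus, family, order = lin.get("genus"), lin.get("family"), lin.get("order")
    cands: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for gid in sorted(host_lineages):
        if gid == host_id:
            continue
        other = host_lineages[gid]
        if other.get("genus") == genus:
            cands["same_genus"].append(gid)
        elif other.get("family") == family:
            cands["same_family"].append(gid)
        if other.get("order") != order:
            cands["different_order"].append(gid)
    return cands


def _metric_value(
    metric: str,
    virus_id: str,
    genome_id: str,
    virus_vectors,
    host_vectors,
    virus_genes,
    host_tables,
) -> float:
    if metric in KMER_METRICS:
        return mae_distance(virus_vectors[metric][virus_id], host_vectors[metric][genome_id])
    if metric == "cai":
        return sequence_cai(virus_genes[virus_id], host_tables[genome_id])
    raise ValueError(f"unknown metric {metric!r}")


def adaptation_experiment(
    viruses: Mapping[str, str],
    hosts: Mapping[str, str],
    virus_host: Mapping[str, str],
    host_lineages: Mapping[str, Lineage],
    metrics: Sequence[str] = ("k1", "k2", "k3", "k4", "cai"),
    n_picks: int = 10,
    strata: Mapping[str, str] | None = None,
    virus_genes: Mapping[str, Sequence[str]] | None = None,
    host_cds: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Quantify virus-host composition adaptation per metric and category.

    For every virus the distance (or CAI) to its true host is computed,
    plus to ``n_picks`` randomly chosen genomes from the same genus, the
    same family (different genus), and a different order than the host.
    Per stratum (default: all viruses together) and metric the K-S
    distance ``D`` between the host distribution and each category's
    pooled distribution is reported.  Categories with fewer than
    ``n_picks`` candidate genomes are skipped with a warning.

    Returns a DataFrame with columns
    ``stratum, metric, category, D, n_virus, n_nonhost``.
    """
    for vid in viruses:
        if vid not in virus_host:
            raise ValueError(f"virus {vid!r} lacks a host assignment")
    if "cai" in metrics and (virus_genes is None or host_cds is None):
        raise ValueError("cai metric requires virus_genes and host_cds")

    rng = np.random.default_rng(seed)
    kmer_ms = [m for m in metrics if m in KMER_METRICS]
    virus_vectors = {
        m: {v: kmer_frequencies(s, KMER_METRICS[m]) for v, s in viruses.items()}
        for m in kmer_ms
    }
    host_vectors = {
        m: {g: kmer_frequencies(s, KMER_METRICS[m]) for g, s in hosts.items()}
        for m in kmer_ms
    }
    host_tables = (
        {g: codon_usage_table(list(host_cds[g])) for g in hosts}
        if "cai" in metrics
        else None
    )

    strata = strata or {}
    host_d: dict[tuple[str, str], list[float]] = {}
    cat_d: dict[tuple[str, str, str], list[float]] = {}
    for vid in sorted(viruses):
        hid = virus_host[vid]
        stratum = strata.get(vid, "all")
        cands = _category_candidates(hid, host_lineages)
        picks: dict[str, list[str]] = {}
        for cat in CATEGORIES:
            pool = cands[cat]
            if len(pool) < n_picks:
                warnings.warn(
                    f"category {cat!r} skipped for virus {vid!r}: "
                    f"{len(pool)} candidates < {n_picks}"
                )
                continue
            picks[cat] = list(rng.choice(pool, size=n_picks, replace=False))
        for metric in metrics:
            val = _metric_value(
                metric, vid, hid, virus_vectors, host_vectors, virus_genes, host_tables
            )
            host_d.setdefault((stratum, metric), []).append(val)
            for cat, gids in picks.items():
                for gid in gids:
                    cat_d.setdefault((stratum, metric, cat), []).append(
                        _metric_value(
                            metric, vid, gid, virus_vectors, host_vectors,
                            virus_genes, host_tables,
                        )
                    )

    rows = []
    for (stratum, metric), hvals in sorted(host_d.items()):
        for cat in CATEGORIES:
            nvals = cat_d.get((stratum, metric, cat))
            if not nvals:
                continue
            rows.append(
                {
                    "stratum": stratum,
                    "metric": metric,
                    "category": cat,
                    "D": ks_statistic(hvals, nvals),
                    "n_virus": len(hvals),
                    "n_nonhost": len(nvals),
                }
            )
    return pd.DataFrame(rows)


def subsample_experiment(
    viruses: Mapping[str, str],
    hosts: Mapping[str, str],
    virus_host: Mapping[str, str],
    host_lineages: Mapping[str, Lineage],
    sizes: Sequence[int] = tuple(range(2000, 20001, 2000)),
    n: int = 1000,
    ks: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect of fragment size on virus-host k-mer distance.

    ``n`` contiguous fragments are drawn per size (virus chosen uniformly
    among genomes at least that long, start uniform); for each fragment
    the distance to the true host and to one random different-order
    genome is computed per k.  Sizes longer than every genome are skipped
    with a warning.

    Returns ``(table, slopes)``: per (k, size) mean host / non-host
    distances, and per k the least-squares slope of distance against
    fragment size.
    """
    rng = np.random.default_rng(seed)
    host_vectors = {
        k: {g: kmer_frequencies(s, k) for g, s in hosts.items()} for k in ks
    }
    vids = sorted(viruses)
    rows = []
    points: dict[tuple[int, str], list[tuple[int, float]]] = {}
    for size in sizes:
        eligible = [v for v in vids if len(viruses[v]) >= size]
        if not eligible:
            warnings.warn(f"size {size} exceeds every genome length; skipped")
            continue
        sums = {k: {"host": [], "nonhost": []} for k in ks}
        for _ in range(n):
            vid = eligible[rng.integers(len(eligible))]
            seq = viruses[vid]
            start = int(rng.integers(0, len(seq) - size + 1))
            frag = seq[start : start + size]
            hid = virus_host[vid]
            others = _category_candidates(hid, host_lineages)["different_order"]
            oid = others[rng.integers(len(others))] if others else None
            for k in ks:
                fv = kmer_frequencies(frag, k)
                d_host = mae_distance(fv, host_vectors[k][hid])
                sums[k]["host"].append(d_host)
                points.setdefault((k, "host"), []).append((size, d_host))
                if oid is not None:
                    d_non = mae_distance(fv, host_vectors[k][oid])
                    sums[k]["nonhost"].append(d_non)
                    points.setdefault((k, "nonhost"), []).append((size, d_non))
        for k in ks:
            rows.append(
                {
                    "k": k,
                    "size": size,
                    "mean_host_distance": float(np.mean(sums[k]["host"])),
                    "mean_nonhost_distance": (
                        float(np.mean(sums[k]["nonhost"])) if sums[k]["nonhost"] else np.nan
                    ),
                    "n": len(sums[k]["host"]),
                }
            )
    slope_rows = []
    for k in ks:
        entry = {"k": k}
        for side in ("host", "nonhost"):
            pts = points.get((k, side), [])
            if len(pts) >= 2:
                x = np.array([p[0] for p in pts], dtype=float)
                y = np.array([p[1] for p in pts], dtype=float)
                slope, intercept = np.polyfit(x, y, 1)
                entry[f"slope_{side}"] = float(slope)
                entry[f"intercept_{side}"] = float(intercept)
            else:
                entry[f"slope_{side}"] = np.nan
                entry[f"intercept_{side}"] = np.nan
        slope_rows.append(entry)
    return pd.DataFrame(rows), pd.DataFrame(slope_rows)


def functional_cai_comparison(
    gene_cai: pd.DataFrame, other_label: str = "other"
) -> pd.DataFrame:
    """Compare gene-level CAI of each functional category against 'other'.

    ``gene_cai`` needs columns ``sequence_id, category, cai``.  For each
    category, sequences carrying genes both in the category and in
    ``other_label`` contribute one paired observation (their per-sequence
    mean CAIs); a Wilcoxon signed-rank test is reported per category.
    """
    required = {"sequence_id", "category", "cai"}
    if not required.issubset(gene_cai.columns):
        raise ValueError(f"gene_cai needs columns {sorted(required)}")
    means = gene_cai.groupby(["sequence_id", "category"])["cai"].mean().unstack()
    rows = []
    for cat in means.columns:
        if cat == other_label or other_label not in means.columns:
            continue
        paired = means[[cat, other_label]].dropna()
        if len(paired) < 3 or (paired[cat] == paired[other_label]).all():
            stat, p = np.nan, np.nan
        else:
            stat, p = stats.wilcoxon(paired[cat], paired[other_label])
        rows.append(
            {
                "category": cat,
                "n_pairs": len(paired),
                "mean_cai": float(paired[cat].mean()) if len(paired) else np.nan,
                "mean_cai_other": (
                    float(paired[other_label].mean()) if len(paired) else np.nan
                ),
                "wilcoxon_stat": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
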