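"""Bipartite virus-host interaction matrix and its modularity.

Rows are virus clusters (VCs), columns are host classes; a cell is 1
when at least one virus of the VC was found in a genome of that class.
Modularity of such a bipartite network is measured with Barber's Q,

    Q = (1/m) * sum_ij (A_ij - k_i d_j / m) * delta(g_i, g_j),

where k_i and d_j are row/column margins and m the number of ones, and
maximised with lp-BRIM: label-propagation seeding followed by BRIM
alternation (fix one side's module labels, optimally reassign the
other).  Significance is assessed against fill-preserving random
permutations of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ModulePartition:
    """Module label per row and per column, with the resulting Q."""

    row_modules: tuple[int, ...]
    col_modules: tuple[int, ...]
    q: float


@dataclass(frozen=True)
class NullModel:
    q_obs: float
    q_perm_min: float
    q_perm_mean: float
    q_perm_max: float
    p_value: float
    n_perm: int


def build_incidence(
    vc_members: Mapping[str, frozenset | set],
    host_class: Mapping[str, str],
    min_vc_size: int = 10,
) -> pd.DataFrame:
    """Binary VC x host-class incidence matrix.

    Only VCs with strictly more than ``min_vc_size`` members enter the
    matrix (small clusters give unstable host-range signal).  Empty rows
    or columns — possible when member host classes collapse — are
    dropped with a warning.
    """
    rows = {}
    for vc_id in sorted(vc_members):
        members = vc_members[vc_id]
        if len(members) <= min_vc_size:
            continue
        classes = set()
        for virus in sorted(members):
            if virus not in host_class:
                raise ValueError(f"virus {virus!r} has no host class")
            classes.add(host_class[virus])
        rows[vc_id] = classes
    if not rows:
        raise ValueError(
            f"no VC has more than {min_vc_size} members; cannot build matrix"
        )
    all_classes = sorted(set().union(*rows.values()))
    matrix = pd.DataFrame(0, index=sorted(rows), columns=all_classes, dtype=int)
    for vc_id, classes in rows.items():
        matrix.loc[vc_id, sorted(classes)] = 1
    empty_rows = matrix.index[matrix.sum(axis=1) == 0]
    empty_cols = matrix.columns[matrix.sum(axis=0) == 0]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(
            f"dropping {len(empty_rows)} empty rows and {len(empty_cols)} empty columns"
        )
        matrix = matrix.drop(index=empty_rows, columns=empty_cols)
    return matrix


def _as_array(matrix) -> np.ndarray:
    arr = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    return arr.astype(float)


def barber_modularity(
    matrix,
    partition: ModulePartition | tuple[Sequence[int], Sequence[int]],
) -> float:
    """Barber's bipartite modularity of a given row/column module partition."""
    A = _as_array(matrix)
    if isinstance(partition, ModulePartition):
        g_rows, g_cols = partition.row_modules, partition.col_modules
    else:
        g_rows, g_cols = partition
    g_rows = np.asarray(g_rows)
    g_cols = np.asarray(g_cols)
    if g_rows.shape[0] != A.shape[0] or g_cols.shape[0] != A.shape[1]:
        raise ValueError("partition does not label every row and column")
    m = A.sum()
    if m == 0:
        raise ValueError("matrix has no interactions (m = 0)")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    B = A - np.outer(k, d) / m
    delta = g_rows[:, None] == g_cols[None, :]
    return float((B * delta).sum() / m)


def _brim_q(B: np.ndarray, m: float, g_rows: np.ndarray, g_cols: np.ndarray) -> float:
    delta = g_rows[:, None] == g_cols[None, :]
    return float((B * delta).sum() / m)


def _assign_side(B_side: np.ndarray, other_labels: np.ndarray,
                 n_modules: int) -> np.ndarray:
    """Optimal module per node of one side given the other side's labels.

    ``B_side`` is (n_nodes, n_other); score of putting node v in module t
    is the sum of B over the other-side nodes labelled t.  A zero-score
    fresh module (index ``n_modules``) lets nodes with only negative
    affinities break away.  Ties broken by lowest module id.
    """
    onehot = np.zeros((other_labels.size, n_modules))
    onehot[np.arange(other_labels.size), other_labels] = 1.0
    scores = B_side @ onehot  # (n_nodes, n_modules)
    scores = np.hstack([scores, np.zeros((scores.shape[0], 1))])
    return np.asarray(np.argmax(scores, axis=1))


def _label_propagation(A: np.ndarray, rng: np.random.Generator,
                       max_rounds: int = 30) -> tuple[np.ndarray, np.ndarray]:
    r, c = A.shape
    g_rows = rng.permutation(r)
    g_cols = np.zeros(c, dtype=int)
    for _ in range(max_rounds):
        prev = (g_rows.copy(), g_cols.copy())
        for j in rng.permutation(c):
            weights = np.bincount(g_rows, weights=A[:, j], minlength=r)
            if weights.max() > 0:
                best = np.flatnonzero(weights == weights.max())
                g_cols[j] = int(rng.choice(best))
        for i in rng.permutation(r):
            weights = np.bincount(g_cols, weights=A[i, :], minlength=r)
            if weights.max() > 0:
                best = np.flatnonzero(weights == weights.max())
                g_rows[i] = int(rng.choice(best))
        if np.array_equal(prev[0], g_rows) and np.array_equal(prev[1], g_cols):
            break
    return g_rows, g_cols


def _compact(g_rows: np.ndarray, g_cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    labels = np.concatenate([g_rows, g_cols])
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv[: g_rows.size], inv[g_rows.size :], uniq.size


def lp_brim(matrix, n_restarts: int = 20, seed: int = 0) -> ModulePartition:
    """Maximise Barber's Q with label propagation + BRIM alternation.

    Each restart seeds row/column modules by label propagation on the
    bipartite graph, then alternates BRIM steps (columns reassigned
    optimally given rows, then rows given columns) until Q stops
    improving.  The best partition over restarts — never worse than the
    trivial single-module partition — is returned; deterministic for a
    given seed.
    """
    A = _as_array(matrix)
    r, c = A.shape
    m = A.sum()
    if m == 0:
        raise ValueError("matrix has no interactions (m = 0)")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    B = A - np.outer(k, d) / m
    rng = np.random.default_rng(seed)

    def _refine(g_rows: np.ndarray, g_cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        g_rows, g_cols, n_mod = _compact(g_rows, g_cols)
        q = _brim_q(B, m, g_rows, g_cols)
        for _ in range(200):
            g_cols = _assign_side(B.T, g_rows, n_mod)
            g_rows, g_cols, n_mod = _compact(g_rows, g_cols)
            g_rows = _assign_side(B, g_cols, n_mod)
            g_rows, g_cols, n_mod = _compact(g_rows, g_cols)
            q_new = _brim_q(B, m, g_rows, g_cols)
            if q_new <= q + 1e-12:
                q = max(q, q_new)
                break
            q = q_new
        return g_rows, g_cols, q

    # trivial one-module partition is the floor
    best_rows = np.zeros(r, dtype=int)
    best_cols = np.zeros(c, dtype=int)
    best_q = _brim_q(B, m, best_rows, best_cols)
    for restart in range(n_restarts):
        if restart == 0:  # deterministic fine-grained start: every row apart
            g_rows, g_cols = np.arange(r), np.full(c, r)
        else:
            g_rows, g_cols = _label_propagation(A, rng)
        g_rows, g_cols, q = _refine(g_rows, g_cols)
        if q > best_q + 1e-12:
            best_rows, best_cols, best_q = g_rows, g_cols, q
    return ModulePartition(
        tuple(int(x) for x in best_rows),
        tuple(int(x) for x in best_cols),
        float(best_q),
    )


def brute_force_max_modularity(matrix) -> float:
    """Exhaustive maximum of Barber's Q over all bipartite partitions.

    Enumerates every labelling of the rows into at most min(r, c) + 1
    modules; given fixed row labels the optimal column assignment
    decomposes per column (each column takes the module with the largest
    summed B, or any empty module when all sums are negative).  Feasible
    for small matrices only — the oracle used to validate lp-BRIM.
    """
    A = _as_array(matrix)
    r, c = A.shape
    m = A.sum()
    if m == 0:
        raise ValueError("matrix has no interactions (m = 0)")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    B = A - np.outer(k, d) / m
    # at most min(r, c) modules can hold columns; one extra module lets
    # rows opt out of every column-bearing module
    n_mod = min(r, min(r, c) + 1)
    if r > 8:
        raise ValueError("exhaustive search limited to 8 rows")
    best = -np.inf
    labels = np.zeros(r, dtype=int)

    def recurse(i: int, used: int) -> None:
        nonlocal best
        if i == r:
            onehot = np.zeros((r, used))
            onehot[np.arange(r), labels] = 1.0
            col_scores = B.T @ onehot  # (c, used)
            q = np.maximum(col_scores.max(axis=1), 0.0).sum() / m
            best = max(best, float(q))
            return
        for lab in range(min(used + 1, n_mod)):
            labels[i] = lab
            recurse(i + 1, max(used, lab + 1))

    recurse(0, 0)
    return best


def shuffle_matrix(matrix, rng: np.random.Generator, scheme: str = "uniform"):
    """Randomise a binary matrix for the permutation null.

    ``uniform`` scatters the m ones uniformly over the grid (fill
    preserved); ``swap`` preserves both margins via checkerboard swaps.
    """
    A = _as_array(matrix)
    r, c = A.shape
    if scheme == "uniform":
        m = int(A.sum())
        flat = np.zeros(r * c)
        flat[rng.choice(r * c, size=m, replace=False)] = 1.0
        return flat.reshape(r, c)
    if scheme == "swap":
        A = A.copy()
        ones = np.argwhere(A == 1)
        n_attempts = 10 * max(len(ones), 1)
        for _ in range(n_attempts):
            (i1, j1), (i2, j2) = ones[rng.choice(len(ones), 2, replace=False)]
            if i1 != i2 and j1 != j2 and A[i1, j2] == 0 and A[i2, j1] == 0:
                A[i1, j1] = A[i2, j2] = 0
                A[i1, j2] = A[i2, j1] = 1
                ones = np.argwhere(A == 1)
        return A
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_null(
    matrix,
    n_perm: int = 99,
    seed: int = 0,
    n_restarts: int = 20,
    scheme: str = "uniform",
) -> tuple[ModulePartition, NullModel]:
    """Observed lp-BRIM modularity against a permuted-matrix null.

    Each permutation redistributes the matrix fill, lp-BRIM is run on it
    (empty rows/columns are kept so Q stays comparable), and the
    empirical p-value is (1 + #{Q_perm >= Q_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = lp_brim(matrix, n_restarts=n_restarts, seed=int(rng.integers(2**31 - 1)))
    q_perm = []
    for _ in range(n_perm):
        perm = shuffle_matrix(matrix, rng, scheme=scheme)
        part = lp_brim(perm, n_restarts=n_restarts, seed=int(rng.integers(2**31 - 1)))
        q_perm.append(part.q)
    q_perm = np.asarray(q_perm)
    p = (1 + int((q_perm >= observed.q).sum())) / (n_perm + 1)
    null = NullModel(
        q_obs=observed.q,
        q_perm_min=float(q_perm.min()),
        q_perm_mean=float(q_perm.mean()),
        q_perm_max=float(q_perm.max()),
        p_value=float(p),
        n_perm=n_perm,
    )
    return observed, null
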