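"""Gene-content clustering of viral genomes into genus-level clusters.

Viral taxonomy below the order level tracks shared gene content well, so
genomes are clustered in two tiers:

1. proteins are grouped into protein clusters (PCs) by Markov clustering
   (MCL) of the reciprocal-best-hit (RBH) similarity graph (score >= 50,
   e-value <= 1e-3);
2. for every genome pair the number of shared PCs is compared with the
   hypergeometric expectation given the two genomes' PC repertoire sizes,
   yielding a significance S = -log10(P * n_pairs); genomes joined by
   edges with S above a threshold are clustered with MCL into virus
   clusters (VCs), which behave approximately like genera.

The significance threshold and MCL inflation are selected by sweeping a
grid and scoring each clustering with the intra-cluster clustering
coefficient (ICCC).  VCs containing a reference genome are putative known
genera; VCs with a complete / circular / >30 kb member but no reference
are putative *new* genera; VCs made only of short fragments are never
called genera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy import stats

MIN_SCORE = 50.0
MAX_EVALUE = 1e-3

LARGE_GENOME_MIN_BP = 30_000

STATUS_KNOWN = "putative_genus_known"
STATUS_NEW = "putative_genus_new"
STATUS_FRAGMENT = "fragment_only"


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.evalue < 0:
            raise ValueError("bit score and e-value must be >= 0")


@dataclass(frozen=True)
class GenomeProfile:
    """Per-genome PC repertoire used for shared-gene significance."""

    genome_id: str
    pcs: frozenset[str]
    gene_count: int

    def __post_init__(self) -> None:
        if len(self.pcs) > self.gene_count:
            raise ValueError(
                f"{self.genome_id}: PC set larger than gene count"
            )


@dataclass(frozen=True)
class Significance:
    p: float
    s: float


@dataclass(frozen=True)
class SequenceMeta:
    """Per-sequence flags consumed by VC classification."""

    circular: bool = False
    complete: bool = False
    length_bp: int = 0
    is_reference: bool = False


@dataclass(frozen=True)
class VirusCluster:
    vc_id: str
    members: frozenset[str]
    contains_reference: bool
    has_large_or_complete: bool
    status: str


def _hits_frame(hits) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        df = hits.rename(
            columns={"qseqid": "query", "sseqid": "subject"}
        )[["query", "subject", "bitscore", "evalue"]].copy()
    else:
        df = pd.DataFrame(
            [(h.query, h.subject, h.bitscore, h.evalue) for h in hits],
            columns=["query", "subject", "bitscore", "evalue"],
        )
    return df


def build_rbh_graph(
    hits: Iterable[SimilarityHit] | pd.DataFrame,
    min_score: float = MIN_SCORE,
    max_evalue: float = MAX_EVALUE,
    protein_to_genome: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Undirected protein graph of reciprocal best hits.

    Hits below ``min_score`` or above ``max_evalue`` are discarded before
    best-hit selection, as are self-hits.  With ``protein_to_genome``
    given, the best hit is taken per subject genome (the standard
    comparative-genomics RBH construction); otherwise a single global
    best hit per query is used.  An edge joins p and q when each is the
    other's best hit; its weight is the mean of the two bit scores.
    """
    df = _hits_frame(hits)
    df = df[
        (df["bitscore"] >= min_score)
        & (df["evalue"] <= max_evalue)
        & (df["query"] != df["subject"])
    ]
    graph = nx.Graph()
    if df.empty:
        return graph
    if protein_to_genome is not None:
        df = df.assign(_sg=df["subject"].map(protein_to_genome))
        group_cols = ["query", "_sg"]
    else:
        group_cols = ["query"]
    df = df.sort_values(
        ["bitscore", "subject"], ascending=[False, True], kind="mergesort"
    )
    best = df.groupby(group_cols, sort=False).first().reset_index()
    best_score = {
        (q, s): b for q, s, b in zip(best["query"], best["subject"], best["bitscore"])
    }
    for (q, s), b in best_score.items():
        if q < s and (s, q) in best_score:
            graph.add_edge(q, s, weight=(b + best_score[(s, q)]) / 2.0)
    return graph


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> list[frozenset]:
    """Markov clustering of a positively weighted undirected graph.

    Column-normalised adjacency (self-loops of weight 1 added), iterating
    expansion (matrix square) and inflation (element-wise power followed
    by renormalisation), pruning entries below ``prune``, until the
    matrix changes by less than ``tol`` or ``max_iter`` rounds.  Clusters
    are the connected components of the limit matrix's support, so every
    node lands in exactly one cluster.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = list(graph.nodes)
    if not nodes:
        return []
    A = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csr")
    A = A.astype(float)
    if A.nnz and A.data.min() <= 0:
        raise ValueError("MCL requires strictly positive edge weights")
    n = len(nodes)
    M = A + sparse.identity(n, format="csr")

    def _normalise(mat: sparse.csr_matrix) -> sparse.csr_matrix:
        sums = np.asarray(mat.sum(axis=0)).ravel()
        sums[sums == 0] = 1.0
        return (mat @ sparse.diags(1.0 / sums)).tocsr()

    M = _normalise(M)
    for _ in range(max_iter):
        X = (M @ M).tocsr()
        X.data = np.power(X.data, inflation)
        X = _normalise(X)
        X.data[X.data < prune] = 0.0
        X.eliminate_zeros()
        X = _normalise(X)
        delta = abs(X - M).max() if (X - M).nnz else 0.0
        M = X
        if delta < tol:
            break
    support = M + M.T
    n_comp, labels = connected_components(support, directed=False)
    clusters: dict[int, set] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), set()).add(node)
    return [frozenset(c) for c in sorted(clusters.values(), key=lambda c: sorted(map(str, c)))]


def protein_clusters(
    hits,
    min_score: float = MIN_SCORE,
    max_evalue: float = MAX_EVALUE,
    inflation: float = 2.0,
    protein_to_genome: Mapping[str, str] | None = None,
) -> dict[str, frozenset]:
    """RBH graph + MCL, returning PC id -> member proteins.

    Proteins with no RBH edge form no PC (singletons carry no shared-gene
    information and are excluded from repertoires).
    """
    graph = build_rbh_graph(hits, min_score, max_evalue, protein_to_genome)
    clusters = [c for c in mcl(graph, inflation=inflation) if len(c) >= 2]
    return {f"PC_{i:05d}": c for i, c in enumerate(sorted(clusters, key=sorted))}


def pair_significance(a: int, b: int, c: int, n: int, n_pairs: int = 1) -> Significance:
    """Hypergeometric significance of c shared PCs between repertoires a and b.

    P is the upper tail P(X >= c) for X hypergeometric(n, a, b): the
    chance of sharing at least c PCs when b PCs are drawn at random from
    a universe of n of which a sit in the first genome.  The significance
    S = max(0, -log10(P * n_pairs)) applies a Bonferroni-style correction
    for the number of genome pairs examined.
    """
    if not (0 <= c <= min(a, b) <= max(a, b) <= n):
        raise ValueError("need 0 <= c <= min(a,b) <= n")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    p = float(stats.hypergeom.sf(c - 1, n, a, b))
    p = min(max(p, 1e-300), 1.0)
    s = max(0.0, -math.log10(p * n_pairs))
    return Significance(p=p, s=s)


def genome_profiles(
    pcs: Mapping[str, frozenset],
    protein_to_genome: Mapping[str, str],
    gene_counts: Mapping[str, int] | None = None,
) -> dict[str, GenomeProfile]:
    """Project PC membership onto genomes (presence/absence of each PC)."""
    per_genome: dict[str, set[str]] = {}
    for pc_id, members in pcs.items():
        for prot in members:
            genome = protein_to_genome[prot]
            per_genome.setdefault(genome, set()).add(pc_id)
    out = {}
    for genome, pcset in sorted(per_genome.items()):
        count = gene_counts[genome] if gene_counts else len(pcset)
        out[genome] = GenomeProfile(genome, frozenset(pcset), count)
    return out


def build_genome_network(
    profiles: Mapping[str, GenomeProfile] | Sequence[GenomeProfile],
    sig_threshold: float = 1.0,
    universe_size: int | None = None,
) -> nx.Graph:
    """Genome graph with an S-weighted edge per significantly similar pair.

    The PC universe defaults to the union of all repertoires; pairs
    sharing no PC never get an edge.  Raising the threshold can only
    remove edges.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.genome_id: p for p in profiles}
    if len(profiles) < 2:
        raise ValueError("need at least two genome profiles")
    ids = sorted(profiles)
    universe = universe_size or len(set().union(*(profiles[g].pcs for g in ids)) or set())
    n_pairs = len(ids) * (len(ids) - 1) // 2
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, gi in enumerate(ids):
        for gj in ids[i + 1 :]:
            shared = len(profiles[gi].pcs & profiles[gj].pcs)
            if shared == 0:
                continue
            sig = pair_significance(
                len(profiles[gi].pcs), len(profiles[gj].pcs), shared, universe, n_pairs
            )
            if sig.s >= sig_threshold:
                graph.add_edge(gi, gj, weight=sig.s, p=sig.p, shared=shared)
    return graph


def cluster_genomes(
    network: nx.Graph, inflation: float = 4.0
) -> tuple[list[frozenset], list[str]]:
    """MCL on the significance-weighted genome graph.

    Returns ``(clusters, unclustered)``; genomes with no significant edge
    are reported as unclustered rather than forced into singletons.
    """
    isolated = sorted(n for n in network.nodes if network.degree(n) == 0)
    sub = network.subgraph(n for n in network.nodes if network.degree(n) > 0)
    zero_weight = [
        (u, v) for u, v, w in sub.edges(data="weight") if w is not None and w <= 0
    ]
    if zero_weight:
        # S = 0 edges can occur at threshold 0; MCL needs positive weights
        sub = nx.Graph(sub)
        for u, v in zero_weight:
            sub[u][v]["weight"] = 1e-9
    clusters = mcl(sub, inflation=inflation) if sub.number_of_nodes() else []
    return clusters, isolated


def iccc(network: nx.Graph, clusters: Sequence[frozenset]) -> float:
    """Intra-cluster clustering coefficient of a partition.

    Mean, over nodes of degree >= 1, of the fraction of a node's
    neighbours that share its cluster — 1.0 when every edge is
    intra-cluster, 0.0 for one-node-per-cluster partitions of a graph
    with edges.
    """
    membership: dict = {}
    for i, cl in enumerate(clusters):
        for node in cl:
            membership[node] = i
    fracs = []
    for node in network.nodes:
        deg = network.degree(node)
        if deg == 0:
            continue
        if node not in membership:
            raise ValueError(f"node {node!r} not covered by the partition")
        same = sum(
            1 for nb in network.neighbors(node) if membership.get(nb) == membership[node]
        )
        fracs.append(same / deg)
    if not fracs:
        raise ValueError("ICCC undefined: every node has degree 0")
    return float(np.mean(fracs))


def sweep_parameters(
    profiles: Mapping[str, GenomeProfile],
    thresholds: Sequence[float] = (1, 5, 10, 20, 30, 40, 50),
    inflations: Sequence[float] | None = None,
    universe_size: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Grid-evaluate (significance threshold, inflation) by ICCC.

    Returns the full grid table and the argmax cell; ties go to the
    lowest threshold, then the lowest inflation.  Cells whose network has
    no edge have undefined ICCC and never win.
    """
    if inflations is None:
        inflations = tuple(np.arange(1.5, 5.0 + 1e-9, 0.25))
    if len(thresholds) == 0 or len(inflations) == 0:
        raise ValueError("empty parameter grid")
    rows = []
    for thr in thresholds:
        network = build_genome_network(profiles, sig_threshold=thr, universe_size=universe_size)
        for infl in inflations:
            clusters, unclustered = cluster_genomes(network, inflation=infl)
            try:
                score = iccc(network, clusters)
            except ValueError:
                score = np.nan
            rows.append(
                {
                    "threshold": float(thr),
                    "inflation": float(infl),
                    "iccc": score,
                    "n_clusters": len(clusters),
                    "n_unclustered": len(unclustered),
                }
            )
    table = pd.DataFrame(rows)
    scored = table.dropna(subset=["iccc"])
    if scored.empty:
        raise ValueError("no parameter cell produced a scorable clustering")
    best = (
        scored.sort_values(
            ["iccc", "threshold", "inflation"], ascending=[False, True, True],
            kind="mergesort",
        )
        .iloc[0]
        .to_dict()
    )
    return table, best


def classify_vcs(
    clusters: Sequence[frozenset],
    metadata: Mapping[str, SequenceMeta],
) -> tuple[list[VirusCluster], dict[str, int]]:
    """Annotate virus clusters and call putative (new) genera.

    A VC is a candidate genus only when at least one member is circular,
    a known complete genome, or larger than 30 kb — this avoids calling
    short genome fragments new genera.  Candidate genera without any
    reference member are *new*.
    """
    out: list[VirusCluster] = []
    for i, members in enumerate(clusters):
        for seq in members:
            if seq not in metadata:
                raise ValueError(f"missing metadata for sequence {seq!r}")
        has_ref = any(metadata[s].is_reference for s in members)
        large = any(
            metadata[s].circular
            or metadata[s].complete
            or metadata[s].length_bp > LARGE_GENOME_MIN_BP
            for s in members
        )
        if has_ref:
            status = STATUS_KNOWN
        elif large:
            status = STATUS_NEW
        else:
            status = STATUS_FRAGMENT
        out.append(
            VirusCluster(
                vc_id=f"VC_{i:04d}",
                members=frozenset(members),
                contains_reference=has_ref,
                has_large_or_complete=large,
                status=status,
            )
        )
    counts = {
        "n_vcs": len(out),
        "n_putative_genera": sum(c.status != STATUS_FRAGMENT for c in out),
        "n_new": sum(c.status == STATUS_NEW for c in out),
        "n_known": sum(c.status == STATUS_KNOWN for c in out),
        "n_fragment_only": sum(c.status == STATUS_FRAGMENT for c in out),
    }
    return out, counts
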