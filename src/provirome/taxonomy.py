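"""Taxonomic affiliation by majority rule and lowest common ancestor.

Viral sequences mined from microbial genomes are affiliated from the
lineages of their similarity hits, and clusters from the affiliations of
their members.  Two rules are used throughout:

* a strict ``>75%`` rank-wise majority rule for affiliating a group from
  its member lineages, and
* LCA (lowest common ancestor) affiliation of a sequence from its set of
  relevant gene hits — the absolute best hit plus every other gene's best
  hit scoring more than 75% of that absolute best.

Lineages are ordered rank tuples; a rank may be :data:`UNASSIGNED`, and no
assigned rank is allowed below an unassigned one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

UNASSIGNED = "unassigned"

#: Default ranks for microbial host lineages (7-rank convention).
HOST_RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

#: Default ranks used for viral lineages.
VIRUS_RANKS: tuple[str, ...] = ("order", "family", "genus")


@dataclass(frozen=True)
class Lineage:
    """An ordered sequence of taxonomic labels, top rank first."""

    ranks: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(self.labels):
            raise ValueError("ranks and labels must have equal length")
        seen_unassigned = False
        for lab in self.labels:
            if lab == UNASSIGNED:
                seen_unassigned = True
            elif seen_unassigned:
                raise ValueError(
                    "assigned rank below an unassigned rank: %r" % (self.labels,)
                )

    def get(self, rank: str) -> str:
        return self.labels[self.ranks.index(rank)]

    @property
    def depth(self) -> int:
        """Number of assigned ranks (contiguous from the top)."""
        d = 0
        for lab in self.labels:
            if lab == UNASSIGNED:
                break
            d += 1
        return d

    @property
    def is_unclassified(self) -> bool:
        """True when not even the top rank could be assigned."""
        return self.depth == 0

    def truncate(self, depth: int) -> "Lineage":
        labels = tuple(self.labels[:depth]) + (UNASSIGNED,) * (len(self.ranks) - depth)
        return Lineage(self.ranks, labels)

    def __str__(self) -> str:  # semicolon-delimited, the on-disk dialect
        return ";".join(self.labels)

    @classmethod
    def from_string(cls, text: str, ranks: Sequence[str]) -> "Lineage":
        parts = [p.strip() for p in text.split(";")]
        if len(parts) < len(ranks):
            parts += [UNASSIGNED] * (len(ranks) - len(parts))
        labels = tuple(p if p else UNASSIGNED for p in parts[: len(ranks)])
        return cls(tuple(ranks), labels)

    @classmethod
    def unassigned(cls, ranks: Sequence[str]) -> "Lineage":
        return cls(tuple(ranks), (UNASSIGNED,) * len(ranks))


@dataclass(frozen=True)
class GeneHit:
    """Best similarity hit of one gene against a reference profile."""

    gene_id: str
    target_id: str
    score: float
    lineage: Lineage = field(compare=False)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("hit score must be >= 0")


def _check_common_ranks(lineages: Sequence[Lineage]) -> tuple[str, ...]:
    ranks = lineages[0].ranks
    for lin in lineages[1:]:
        if lin.ranks != ranks:
            raise ValueError("lineages use inconsistent rank systems")
    return ranks


def affiliate_members(lineages: Sequence[Lineage], q: float = 0.75) -> Lineage:
    """Affiliate a group from member lineages with a strict >q majority rule.

    At each rank, top-down, the group takes the label carried by strictly
    more than ``q`` of *all* members (members unassigned at that rank stay
    in the denominator).  The first rank with no such label stops the
    descent; it and everything below are left unassigned.
    """
    if len(lineages) == 0:
        raise ValueError("cannot affiliate an empty member set")
    ranks = _check_common_ranks(lineages)
    n = len(lineages)
    labels: list[str] = []
    for level in range(len(ranks)):
        counts = Counter(
            lin.labels[level] for lin in lineages if lin.labels[level] != UNASSIGNED
        )
        winner = None
        for lab, cnt in counts.items():
            if cnt / n > q:
                winner = lab
                break
        if winner is None:
            break
        labels.append(winner)
    return Lineage(ranks, tuple(labels) + (UNASSIGNED,) * (len(ranks) - len(labels)))


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Lowest common ancestor: deepest rank on which all lineages agree."""
    if len(lineages) == 0:
        raise ValueError("LCA of an empty set is undefined")
    ranks = _check_common_ranks(lineages)
    labels: list[str] = []
    for level in range(len(ranks)):
        seen = {lin.labels[level] for lin in lineages}
        if len(seen) != 1 or UNASSIGNED in seen:
            break
        labels.append(seen.pop())
    return Lineage(ranks, tuple(labels) + (UNASSIGNED,) * (len(ranks) - len(labels)))


def best_hits_per_gene(hits: Iterable[GeneHit]) -> list[GeneHit]:
    """Keep the single best hit per gene (score ties broken by target id)."""
    best: dict[str, GeneHit] = {}
    for hit in hits:
        cur = best.get(hit.gene_id)
        if (
            cur is None
            or hit.score > cur.score
            or (hit.score == cur.score and hit.target_id < cur.target_id)
        ):
            best[hit.gene_id] = hit
    return [best[g] for g in sorted(best)]


def relevant_hits(
    hits: Sequence[GeneHit], rel_threshold: float = 0.75
) -> list[GeneHit]:
    """The absolute best hit plus per-gene best hits above the score cut."""
    hits = best_hits_per_gene(hits)
    if not hits:
        return []
    best_score = max(h.score for h in hits)
    return [
        h for h in hits
        if h.score > rel_threshold * best_score or h.score == best_score
    ]


def affiliate_sequence(
    hits: Sequence[GeneHit],
    rel_threshold: float = 0.75,
    ranks: Sequence[str] = VIRUS_RANKS,
) -> Lineage:
    """Affiliate a sequence to the LCA of its relevant gene hits.

    ``hits`` is the per-gene best hit set.  The relevant set is the
    absolute best hit over the whole sequence plus every other gene's best
    hit with score strictly greater than ``rel_threshold`` times that
    absolute best score.  With no hits the sequence stays unassigned.
    The result does not depend on gene order or on rescaling all scores
    by a positive constant.
    """
    relevant = relevant_hits(hits, rel_threshold)
    if not relevant:
        return Lineage.unassigned(ranks)
    return lca([h.lineage for h in relevant])


def affiliate_vc(member_lineages: Sequence[Lineage], q: float = 0.75) -> Lineage:
    """Affiliate a virus cluster from its member affiliations (>75% rule).

    A fully inconsistent cluster (no rank assigned) is rendered as
    ``unclassified`` downstream; check :attr:`Lineage.is_unclassified`.
    """
    if len(member_lineages) == 0:
        raise ValueError("cannot affiliate an empty virus cluster")
    return affiliate_members(member_lineages, q=q)


def read_lineages(
    path, ranks: Sequence[str] = HOST_RANKS
) -> dict[str, Lineage]:
    """Read a two-column TSV ``id<TAB>rank1;rank2;...`` into a mapping."""
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, _, lin = line.partition("\t")
            out[name] = Lineage.from_string(lin, ranks)
    return out


def write_lineages(path, lineages: Mapping[str, Lineage]) -> None:
    with open(path, "w") as fh:
        for name in sorted(lineages):
            fh.write(f"{name}\t{lineages[name]}\n")
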