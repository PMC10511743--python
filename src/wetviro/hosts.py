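"""Virus-host linkage: spacer-hit filtering and consensus taxonomy.

Host evidence arrives as tabular spacer/protospacer alignments plus
per-source lineage predictions; this module applies the exact-match
filter and resolves multiple predictions to their deepest common rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered ranked lineage, domain -> species, truncated at the deepest
    assigned rank. An empty lineage is the "unknown" sentinel."""

    ranks: tuple = ()

    def __post_init__(self):
        ranks = tuple(r for r in self.ranks)
        if len(ranks) > len(RANKS):
            raise ValueError("lineage deeper than species")
        if any(not r for r in ranks):
            raise ValueError("empty rank inside lineage (gap ranks forbidden)")
        object.__setattr__(self, "ranks", ranks)

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "TaxonomyLineage":
        if text.strip().lower() in ("", "unknown"):
            return cls(())
        parts = [p.strip() for p in text.split(sep)]
        while parts and not parts[-1]:
            parts.pop()
        return cls(tuple(parts))

    def to_string(self, sep: str = ";") -> str:
        return "unknown" if self.is_unknown else sep.join(self.ranks)

    @property
    def is_unknown(self) -> bool:
        return len(self.ranks) == 0

    @property
    def depth(self) -> int:
        return len(self.ranks)

    def at_rank(self, rank: str) -> str | None:
        i = RANKS.index(rank)
        return self.ranks[i] if i < len(self.ranks) else None

    def is_prefix_of(self, other: "TaxonomyLineage") -> bool:
        return self.ranks == other.ranks[: len(self.ranks)]


UNKNOWN = TaxonomyLineage(())


@dataclass(frozen=True)
class SpacerHit:
    """One spacer/protospacer alignment against a vOTU."""

    spacer_id: str
    source: str  # mag | unbinned_contig | spacer_db
    source_lineage: TaxonomyLineage
    votu_id: str
    mismatches: int
    gaps: int
    align_len: int
    spacer_len: int
    evalue: float = 0.0

    def __post_init__(self):
        if self.align_len > self.spacer_len:
            raise ValueError("alignment longer than the spacer")
        if self.mismatches < 0 or self.gaps < 0:
            raise ValueError("negative mismatch/gap count")


def filter_spacer_hits(
    hits: Iterable[SpacerHit], max_mismatches: int = 1
) -> list[SpacerHit]:
    """Accept hits spanning the full spacer with at most one mismatch and
    no gaps."""
    return [
        h
        for h in hits
        if h.mismatches <= max_mismatches
        and h.gaps == 0
        and h.align_len == h.spacer_len
    ]


def consensus_host(predictions: Sequence[TaxonomyLineage]) -> TaxonomyLineage:
    """Resolve several host predictions to their deepest common rank.

    A single prediction is returned unchanged. With several, the lineage
    is truncated at the deepest rank where all agree; disagreement at the
    domain rank yields the unknown sentinel. Order-invariant and
    idempotent; the result is a prefix of every input.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no host predictions supplied")
    if len(predictions) == 1:
        return predictions[0]

    depth = 0
    max_depth = min(p.depth for p in predictions)
    first = predictions[0]
    while depth < max_depth:
        name = first.ranks[depth]
        if all(p.ranks[depth] == name for p in predictions[1:]):
            depth += 1
        else:
            break
    return TaxonomyLineage(first.ranks[:depth])


def host_assignment_summary(
    assignments: Mapping[str, TaxonomyLineage],
    total_votus: int | None = None,
) -> dict:
    """Fraction of vOTUs with a named host at the domain and phylum ranks.

    ``total_votus`` defaults to the number of assignment entries; pass the
    full catalog size when some vOTUs have no prediction at all.
    """
    n = len(assignments) if total_votus is None else int(total_votus)
    if n < len(assignments):
        raise ValueError("total_votus smaller than the assignment table")
    if n == 0:
        return {"domain": 0.0, "phylum": 0.0, "n": 0}
    domain = sum(1 for lin in assignments.values() if lin.depth >= 1)
    phylum = sum(1 for lin in assignments.values() if lin.depth >= 2)
    return {"domain": domain / n, "phylum": phylum / n, "n": n}
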