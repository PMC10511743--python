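"""Viral genome catalog construction.

Builds the dereplicated vOTU set from per-contig predictor evidence:
a multi-tool consensus filter, a size/circularity filter, single-linkage
dereplication over a precomputed ANI/breadth pair table, and the
integrase x circularity partition used for lifestyle summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Predictor names accepted in ``tool_predictions``.
KNOWN_PREDICTORS = frozenset(
    {"virsorter", "virsorter2", "vibrant", "deepvirfinder", "seeker"}
)

DEFAULT_MIN_TOOLS = 2
DEFAULT_MIN_LENGTH = 10_000
DEFAULT_MIN_ANI = 0.95
DEFAULT_MIN_BREADTH = 0.85


@dataclass(frozen=True)
class GenomeCatalogEntry:
    """One vOTU or MAG with the flags the pipeline filters on."""

    id: str
    length_bp: int
    circular: bool = False
    tool_predictions: frozenset = frozenset()
    integrase: bool = False
    source: str = "virome"
    host_lineage: str = ""

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: length must be positive")
        if self.source not in ("virome", "metagenome"):
            raise ValueError(f"{self.id}: unknown source {self.source!r}")
        object.__setattr__(
            self, "tool_predictions", frozenset(self.tool_predictions)
        )


@dataclass(frozen=True)
class AniPair:
    """Undirected ANI/alignment-breadth evidence between two genomes."""

    id_a: str
    id_b: str
    ani: float
    breadth: float

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("pair must join two distinct genomes")
        if not (0.0 <= self.ani <= 1.0 and 0.0 <= self.breadth <= 1.0):
            raise ValueError("ani and breadth must lie in [0, 1]")


@dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple = field(default_factory=tuple)


def consensus_viral_filter(
    entries: Iterable[GenomeCatalogEntry],
    min_tools: int = DEFAULT_MIN_TOOLS,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[str]:
    """Return ids predicted viral by >= ``min_tools`` predictors that are
    either circular or at least ``min_length`` bp long."""
    kept = []
    for e in entries:
        if len(e.tool_predictions) >= min_tools and (
            e.circular or e.length_bp >= min_length
        ):
            kept.append(e.id)
    return kept


class _UnionFind:
    def __init__(self, ids):
        self._parent = {i: i for i in ids}

    def find(self, x):
        p = self._parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra


def dereplicate(
    pairs: Iterable[AniPair | tuple],
    lengths: Mapping[str, int],
    min_ani: float = DEFAULT_MIN_ANI,
    min_breadth: float = DEFAULT_MIN_BREADTH,
) -> list[Cluster]:
    """Single-linkage clusters over pairs with ani >= ``min_ani`` and
    breadth >= ``min_breadth``; representative is the longest member
    (ties broken lexicographically by id).

    ``pairs`` may be :class:`AniPair` objects or ``(id_a, id_b, ani,
    breadth)`` tuples, treated as undirected. Every genome in ``lengths``
    becomes a cluster even if it appears in no pair. Unknown ids in the
    pair table raise ``ValueError``.
    """
    uf = _UnionFind(lengths.keys())
    for p in pairs:
        if not isinstance(p, AniPair):
            p = AniPair(*p)
        for gid in (p.id_a, p.id_b):
            if gid not in lengths:
                raise ValueError(f"pair references unknown genome {gid!r}")
        if p.ani >= min_ani and p.breadth >= min_breadth:
            uf.union(p.id_a, p.id_b)

    groups: dict[str, list[str]] = {}
    for gid in lengths:
        groups.setdefault(uf.find(gid), []).append(gid)

    clusters = []
    for members in groups.values():
        rep = min(members, key=lambda g: (-lengths[g], g))
        clusters.append(Cluster(representative=rep, members=tuple(sorted(members))))
    clusters.sort(key=lambda c: c.representative)
    return clusters


def partition_by_integrase(
    entries: Sequence[GenomeCatalogEntry],
) -> pd.DataFrame:
    """Label each entry by its integrase x circularity partition cell.

    Returns a frame with columns ``id``, ``integrase``, ``circular`` and
    ``label`` (e.g. ``integrase+/circular``); cell counts are conserved:
    label counts always sum to the number of input entries.
    """
    rows = [
        {
            "id": e.id,
            "integrase": bool(e.integrase),
            "circular": bool(e.circular),
            "label": (
                ("integrase+" if e.integrase else "integrase-")
                + "/"
                + ("circular" if e.circular else "linear")
            ),
        }
        for e in entries
    ]
    return pd.DataFrame(rows, columns=["id", "integrase", "circular", "label"])


def integrase_fraction(entries: Sequence[GenomeCatalogEntry]) -> float:
    """Fraction of entries carrying an integrase flag."""
    entries = list(entries)
    if not entries:
        raise ValueError("empty catalog")
    part = partition_by_integrase(entries)
    return float(part["integrase"].mean())
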