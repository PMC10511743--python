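"""Evidence filters for lysogeny and prophage activity.

Candidate prophage-bearing contigs are screened by virome read coverage,
candidate lysogenic vOTUs by alignment thresholds against those contigs,
integrated prophages by differential coverage against their flanking host
region, and integrase enrichment across detection epochs by a Pearson
chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

MIN_COVERED_BP = 1_000
MIN_PCT_IDENTITY = 90.0
MAX_EVALUE = 1e-100
MIN_FLANK_BP = 10_000
MIN_ALIGN_BP = 10_000

#: coverage-ratio threshold above which a prophage counts as active
DEFAULT_ACTIVITY_RATIO = 1.65


@dataclass(frozen=True)
class ContigCoverage:
    contig_id: str
    contig_len: int
    covered_bases: int

    def __post_init__(self):
        if self.covered_bases > self.contig_len:
            raise ValueError("covered bases exceed contig length")
        if self.covered_bases < 0 or self.contig_len <= 0:
            raise ValueError("invalid coverage record")

    @property
    def breadth(self) -> float:
        return self.covered_bases / self.contig_len


@dataclass(frozen=True)
class LysogenAlignment:
    """BLAST-style alignment of a vOTU against a cellular contig.

    ``flank_len`` is the total contig span outside the aligned section.
    """

    votu_id: str
    contig_id: str
    pct_identity: float
    align_len: int
    evalue: float
    flank_len: int

    def __post_init__(self):
        if self.flank_len < 0 or self.align_len <= 0:
            raise ValueError("invalid alignment spans")


@dataclass(frozen=True)
class ProphageCoverage:
    """Read coverage inside a prophage span (0-based half-open on its
    contig) versus the flanking host region."""

    mag_id: str
    contig_id: str
    start: int
    end: int
    prophage_cov: float
    flank_cov: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid prophage coordinates")
        if self.prophage_cov < 0 or self.flank_cov < 0:
            raise ValueError("coverages must be non-negative")


def candidate_prophage_contigs(
    coverages: Iterable[ContigCoverage], min_covered: int = MIN_COVERED_BP
) -> list[str]:
    """Contigs with >= ``min_covered`` bp covered by virome reads but not
    100% breadth — partial coverage suggesting an embedded viral region."""
    return [
        c.contig_id
        for c in coverages
        if c.covered_bases >= min_covered and c.breadth < 1.0
    ]


def lysogen_alignment_filter(
    alignments: Iterable[LysogenAlignment],
    min_identity: float = MIN_PCT_IDENTITY,
    max_evalue: float = MAX_EVALUE,
    min_flank: int = MIN_FLANK_BP,
    min_align: int = MIN_ALIGN_BP,
) -> list[LysogenAlignment]:
    """Keep alignments with identity > 90%, e-value <= 1e-100, more than
    10 kb of flanking contig and an aligned section of at least 10 kb."""
    return [
        a
        for a in alignments
        if a.pct_identity > min_identity
        and a.evalue <= max_evalue
        and a.flank_len > min_flank
        and a.align_len >= min_align
    ]


def prophage_activity(
    p: ProphageCoverage, ratio_threshold: float = DEFAULT_ACTIVITY_RATIO
) -> tuple[bool, float]:
    """Prophage-to-flank coverage ratio and whether it clears the activity
    threshold. Zero flank coverage leaves the ratio undefined (NaN,
    inactive)."""
    if p.flank_cov == 0:
        return False, float("nan")
    ratio = p.prophage_cov / p.flank_cov
    return ratio >= ratio_threshold, ratio


def integrase_enrichment_test(counts) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table
    of integrase presence x detection epoch."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margins")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
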