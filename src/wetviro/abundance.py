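"""Read-mapping summaries to presence, abundance and community structure.

Mapping evidence arrives as long-format records (one row per genome x
sample). Relative abundance is mapped reads over total sample reads;
presence uses genome breadth (covered fraction) with assay-specific
cutoffs: 80% for viromes/metagenomes per sample, 50% in all replicate
tubes for SIP fractions. Trajectories (richness, biomass) are summarized
per plot and time with OLS trends, and community structure via
Bray-Curtis dissimilarity and principal coordinates analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import TrendResult, linear_trend, sem

VIROME_BREADTH_CUTOFF = 0.80
SIP_BREADTH_CUTOFF = 0.50
SIP_N_REPLICATES = 3

MAPPING_COLUMNS = [
    "genome_id",
    "plot",
    "time_h",
    "assay",
    "treatment",
    "fraction_index",
    "mapped_reads",
    "covered_bases",
    "genome_length",
    "sample_total_reads",
]

_SAMPLE_KEY = ["plot", "time_h", "treatment", "fraction_index"]


def validate_mapping(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MAPPING_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"mapping table missing columns: {missing}")
    if (records["covered_bases"] > records["genome_length"]).any():
        raise ValueError("covered_bases exceeds genome_length")
    if (records["mapped_reads"] > records["sample_total_reads"]).any():
        raise ValueError("mapped_reads exceeds sample_total_reads")
    return records


def relative_abundance(records: pd.DataFrame) -> pd.DataFrame:
    """Genome x sample relative abundance (mapped / total sample reads).

    Columns are a MultiIndex over (plot, time_h, treatment,
    fraction_index); genome/sample pairs without a record are zero.
    Raises if any sample reports zero total reads.
    """
    validate_mapping(records)
    zero = records.loc[records["sample_total_reads"] <= 0, _SAMPLE_KEY]
    if len(zero):
        raise ValueError(
            f"sample has zero total reads: {tuple(zero.iloc[0])}"
        )
    rec = records.copy()
    rec["rel_abund"] = rec["mapped_reads"] / rec["sample_total_reads"]
    wide = rec.pivot_table(
        index="genome_id",
        columns=_SAMPLE_KEY,
        values="rel_abund",
        aggfunc="sum",
        fill_value=0.0,
    )
    return wide


def presence_calls(
    records: pd.DataFrame,
    assay: str,
    breadth_cutoff: float | None = None,
    n_replicates: int = SIP_N_REPLICATES,
) -> pd.DataFrame:
    """Boolean presence matrix under the assay's breadth rule.

    virome / metagenome: present per (plot, time_h) iff breadth >= 0.80
    in that sample. sip_fraction: present per (treatment, time_h) iff the
    tube-level breadth (max over fractions) reaches 0.50 in all
    ``n_replicates`` plots of that treatment and time.
    """
    validate_mapping(records)
    rec = records[records["assay"] == assay].copy()
    if assay in ("virome", "metagenome"):
        cutoff = VIROME_BREADTH_CUTOFF if breadth_cutoff is None else breadth_cutoff
        rec["breadth"] = rec["covered_bases"] / rec["genome_length"]
        rec["present"] = rec["breadth"] >= cutoff
        wide = rec.pivot_table(
            index="genome_id",
            columns=["plot", "time_h"],
            values="present",
            aggfunc="any",
            fill_value=False,
        )
        return wide.astype(bool)
    if assay == "sip_fraction":
        cutoff = SIP_BREADTH_CUTOFF if breadth_cutoff is None else breadth_cutoff
        rec["breadth"] = rec["covered_bases"] / rec["genome_length"]
        tube = (
            rec.groupby(["genome_id", "treatment", "time_h", "plot"])["breadth"]
            .max()
            .ge(cutoff)
        )
        n_pass = tube.groupby(["genome_id", "treatment", "time_h"]).sum()
        wide = (
            n_pass.ge(n_replicates)
            .rename("present")
            .reset_index()
            .pivot_table(
                index="genome_id",
                columns=["treatment", "time_h"],
                values="present",
                aggfunc="any",
                fill_value=False,
            )
        )
        return wide.astype(bool)
    raise ValueError(f"unknown assay {assay!r}")


@dataclass(frozen=True)
class SeriesSummary:
    """Per-plot series, its cross-plot mean +/- SEM, and the OLS trend."""

    per_plot: pd.DataFrame  # columns plot, time_h, value
    per_time: pd.DataFrame  # columns time_h, mean, sem, n_plots
    trend: TrendResult | None


def _summarize_series(per_plot: pd.DataFrame) -> SeriesSummary:
    per_time = (
        per_plot.groupby("time_h")["value"]
        .agg(mean="mean", sem=sem, n_plots="count")
        .reset_index()
    )
    trend = None
    if per_plot["time_h"].nunique() >= 2:
        trend = linear_trend(per_plot["time_h"], per_plot["value"])
    return SeriesSummary(per_plot=per_plot, per_time=per_time, trend=trend)


def richness_series(presence: pd.DataFrame) -> SeriesSummary:
    """Unique present genomes per plot and time from a virome presence
    matrix (columns (plot, time_h)); trend fitted on per-plot points."""
    counts = presence.sum(axis=0)
    per_plot = counts.rename("value").reset_index()
    per_plot.columns = ["plot", "time_h", "value"]
    per_plot["value"] = per_plot["value"].astype(int)
    return _summarize_series(per_plot)


def biomass_series(
    dna_yields: pd.DataFrame, viral_read_fraction: pd.DataFrame
) -> SeriesSummary:
    """Viral DNA per gram of soil: extraction yield x viral read fraction.

    Both inputs are long frames keyed by (plot, time_h) with columns
    ``yield_ng_per_g`` and ``viral_read_fraction`` respectively.
    """
    merged = dna_yields.merge(viral_read_fraction, on=["plot", "time_h"])
    if (merged["yield_ng_per_g"] < 0).any():
        raise ValueError("DNA yields must be non-negative")
    if not merged["viral_read_fraction"].between(0, 1).all():
        raise ValueError("viral read fraction must lie in [0, 1]")
    per_plot = merged[["plot", "time_h"]].copy()
    per_plot["value"] = merged["yield_ng_per_g"] * merged["viral_read_fraction"]
    return _summarize_series(per_plot)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(x, y) = sum |x - y| / sum (x + y). A pair of all-zero samples gets
    0; an all-zero sample versus a non-zero one gets 1 (flagged case).
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two samples")
    n = x.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[:, i] + x[:, j]).sum()
            if denom == 0:
                d = 0.0
            else:
                d = np.abs(x[:, i] - x[:, j]).sum() / denom
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=matrix.columns, columns=matrix.columns)


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    variance_explained: np.ndarray  # fractions over positive eigenvalues
    zero_samples: tuple = ()


def bray_curtis_pcoa(matrix: pd.DataFrame) -> PcoaResult:
    """Bray-Curtis dissimilarity followed by classical PCoA.

    Eigendecomposition of the double-centered squared-dissimilarity
    matrix; negative eigenvalues are reported as-is, variance fractions
    are taken over the positive eigenvalues only. All-zero samples are
    listed in ``zero_samples``.
    """
    dist = bray_curtis(matrix)
    zero = tuple(c for c in matrix.columns if matrix[c].sum() == 0)
    d2 = dist.to_numpy() ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    var = np.zeros_like(eigvals)
    if pos.any():
        var[pos] = eigvals[pos] / eigvals[pos].sum()
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=axes),
        eigenvalues=eigvals,
        variance_explained=var,
        zero_samples=zero,
    )


def aggregate_by_flag(
    matrix: pd.DataFrame, flags: Mapping[str, object]
) -> dict[str, pd.DataFrame]:
    """Sum relative abundance and count genomes per flag value per sample.

    Every genome in the matrix must be flagged; per-sample class sums
    conserve the column totals.
    """
    missing = [g for g in matrix.index if g not in flags]
    if missing:
        raise ValueError(f"genomes without a flag: {missing[:5]}")
    groups = pd.Series({g: flags[g] for g in matrix.index}, name="flag")
    summed = matrix.groupby(groups).sum()
    counts = (matrix > 0).groupby(groups).sum()
    return {"abundance": summed, "counts": counts}
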