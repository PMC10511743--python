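"""Virion-based model of viral contribution to microbial mortality.

Viral DNA mass per gram of soil is converted to virion counts from the
mean viral genome length, 16S rRNA copy loss is converted to cells died,
and their ratio across a grid of burst sizes gives the percent of
microbial mortality attributable to viral lysis, reported per time point
and cumulatively.

Note on direction: cells lysed are computed as virions *divided by* the
burst size — each lysis event releases ``burst_size`` virions, so a given
virion pool implies fewer lysed cells at larger burst sizes. The
contribution is therefore largest at burst size 1 and exactly inversely
proportional to the burst size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import TrendResult, linear_trend

AVOGADRO = 6.0221e23  # molecules / mol
BP_MOLAR_MASS = 660.0  # g / mol per base pair
NG_PER_G = 1.0e9

DEFAULT_RRNA_COPIES_PER_CELL = 6.0
DEFAULT_BURST_SIZES = (1.0, 10.0, 25.0, 50.0, 100.0, 200.0)
#: mean vOTU genome length (bp) used when none is supplied
DEFAULT_MEAN_GENOME_LEN_BP = 2.1254e4


@dataclass(frozen=True)
class MortalityInput:
    """Per-time inputs for the mortality model (one plot or plot-mean)."""

    time_h: tuple
    viral_dna_ng_per_g: tuple
    rrna_loss_rate: tuple  # copies g^-1 day^-1, aligned with time_h
    mean_genome_len_bp: float = DEFAULT_MEAN_GENOME_LEN_BP
    rrna_copies_per_cell: float = DEFAULT_RRNA_COPIES_PER_CELL
    burst_sizes: tuple = DEFAULT_BURST_SIZES

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if len(self.viral_dna_ng_per_g) != t.size or len(self.rrna_loss_rate) != t.size:
            raise ValueError("input series must align with the time axis")
        if min(self.viral_dna_ng_per_g, default=0.0) < 0:
            raise ValueError("viral DNA must be non-negative")
        if min(self.burst_sizes, default=1.0) < 1:
            raise ValueError("burst sizes must be >= 1")
        if self.mean_genome_len_bp <= 0:
            raise ValueError("genome length must be positive")

    @property
    def days_elapsed(self) -> tuple:
        return tuple(t / 24.0 for t in self.time_h)


def virions_from_dna(x_ng, genome_len_bp: float):
    """Virions per gram of soil from viral DNA mass (ng/g) and mean genome
    length (bp): X * N_A / (N * 660 g/mol * 1e9 ng/g)."""
    if genome_len_bp <= 0:
        raise ValueError("genome length must be positive")
    x = np.asarray(x_ng, dtype=float)
    if np.any(x < 0):
        raise ValueError("DNA mass must be non-negative")
    out = x * AVOGADRO / (genome_len_bp * BP_MOLAR_MASS * NG_PER_G)
    return float(out) if np.isscalar(x_ng) else out


def cells_died(loss_rate, days, copies_per_cell: float = DEFAULT_RRNA_COPIES_PER_CELL):
    """Cells lost per gram: 16S copy loss rate x days / copies per cell."""
    if copies_per_cell <= 0:
        raise ValueError("rRNA copies per cell must be positive")
    out = np.asarray(loss_rate, dtype=float) * np.asarray(days, dtype=float) / copies_per_cell
    return float(out) if np.isscalar(loss_rate) and np.isscalar(days) else out


def viral_contribution(virions, burst_size: float, cells: float) -> float:
    """Percent of microbial mortality attributable to viral lysis.

    cells_lysed = virions / burst_size; contribution = 100 * lysed/cells.
    Exactly linear: contribution(burst b) == contribution(burst 1) / b.
    Raises for non-positive ``cells`` (undefined denominator).
    """
    if burst_size < 1:
        raise ValueError("burst size must be >= 1")
    if cells <= 0:
        raise ValueError("cells died must be positive (undefined otherwise)")
    return 100.0 * (virions / burst_size) / cells


def cumulative_contribution(per_time: Sequence[float]) -> np.ndarray:
    """Running sum of per-time contributions, in time order."""
    return np.cumsum(np.asarray(per_time, dtype=float))


def contribution_table(inputs: MortalityInput, cumulative_days: bool = True) -> pd.DataFrame:
    """Per-time and cumulative contribution for every burst size.

    Time points with zero elapsed days or zero loss rate have an undefined
    contribution and are reported as NaN with ``defined = False`` rather
    than dropped. ``cumulative_days=False`` uses the interval since the
    previous time point in the denominator instead of days since wet-up.
    """
    t = np.asarray(inputs.time_h, dtype=float)
    days = t / 24.0
    if not cumulative_days:
        days = np.diff(days, prepend=0.0)
    virions = virions_from_dna(
        np.asarray(inputs.viral_dna_ng_per_g), inputs.mean_genome_len_bp
    )
    rows = []
    for b in inputs.burst_sizes:
        per_time = np.full(t.size, np.nan)
        for i in range(t.size):
            dead = inputs.rrna_loss_rate[i] * days[i] / inputs.rrna_copies_per_cell
            if dead > 0:
                per_time[i] = 100.0 * (virions[i] / b) / dead
        defined = ~np.isnan(per_time)
        cumul = np.cumsum(np.where(defined, per_time, 0.0))
        cumul[~defined & (np.arange(t.size) == 0)] = np.nan
        for i in range(t.size):
            rows.append(
                {
                    "time_h": inputs.time_h[i],
                    "burst_size": b,
                    "virions_per_g": virions[i],
                    "contribution_pct": per_time[i],
                    "cumulative_pct": cumul[i],
                    "defined": bool(defined[i]),
                }
            )
    return pd.DataFrame(rows)


def genome_length_sensitivity(
    x_ng: float,
    length_grid_bp: Sequence[float],
    burst_size: float,
    cells: float,
) -> TrendResult:
    """Log-log OLS of contribution on genome length, all else fixed.

    The model is exactly proportional to 1/N, so the slope is -1 and
    r = -1 for any grid spanning distinct lengths.
    """
    grid = np.asarray(length_grid_bp, dtype=float)
    if grid.size < 3:
        raise ValueError("need at least three genome lengths")
    if np.any(grid <= 0):
        raise ValueError("genome lengths must be positive")
    contrib = np.array(
        [viral_contribution(virions_from_dna(x_ng, n), burst_size, cells) for n in grid]
    )
    return linear_trend(np.log10(grid), np.log10(contrib))
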