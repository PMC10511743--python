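"""Temporal response classification of persistent vOTUs.

A vOTU present in three or more time points within one field plot is
"persistent" and is assigned to exactly one of five response categories
based on when it is detected along the ordered time axis
(default 0, 3, 24, 48, 72, 168 h).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hosts import TaxonomyLineage

DEFAULT_TIME_POINTS_H = (0, 3, 24, 48, 72, 168)
CATEGORIES = ("early", "late", "ubiquitous", "zero_and_168", "other")

#: default fraction of the early-window mean below which a late abundance
#: still counts as "drastically decreased" for the early category
DEFAULT_DRASTIC_DROP_FRAC = 0.1

MIN_PERSISTENT_TIME_POINTS = 3


def persistent_filter(
    presence: pd.DataFrame, min_time_points: int = MIN_PERSISTENT_TIME_POINTS
) -> pd.DataFrame:
    """Subset a genome x time boolean frame (one plot) to rows present in
    at least ``min_time_points`` time points."""
    counts = presence.astype(bool).sum(axis=1)
    return presence.loc[counts >= min_time_points]


def classify_response(
    values: Sequence[float],
    time_points_h: Sequence[int] = DEFAULT_TIME_POINTS_H,
    drastic_drop_frac: float = DEFAULT_DRASTIC_DROP_FRAC,
) -> str:
    """Assign a persistent per-plot trajectory to a response category.

    ``values`` is ordered along ``time_points_h`` and may be boolean
    presence or relative abundance (presence means value > 0). Categories
    are checked in fixed precedence so they are mutually exclusive:

    1. ``ubiquitous`` — present at every time point.
    2. ``early`` — present at 0, 3 and 24 h; at 48 h and later either
       absent or below ``drastic_drop_frac`` times the 0-24 h mean.
    3. ``late`` — absent through 24 h, first detected at 48 h.
    4. ``zero_and_168`` — present at 0 h and 168 h and at least one other
       time point (and not ubiquitous).
    5. ``other``.

    With ``drastic_drop_frac = 0`` the early rule demands literal absence
    after 24 h. Raises ``ValueError`` for non-persistent vectors.
    """
    x = np.asarray(values, dtype=float)
    times = list(time_points_h)
    if x.size != len(times):
        raise ValueError("vector length does not match the time axis")
    present = x > 0
    if present.sum() < MIN_PERSISTENT_TIME_POINTS:
        raise ValueError("vector is not persistent (fewer than 3 detections)")

    early_idx = [i for i, t in enumerate(times) if t <= 24]
    late_idx = [i for i, t in enumerate(times) if t > 24]
    i0, i_last = 0, len(times) - 1

    if present.all():
        return "ubiquitous"

    if all(present[i] for i in early_idx):
        cutoff = drastic_drop_frac * x[early_idx].mean()
        if all((not present[i]) or x[i] < cutoff for i in late_idx):
            return "early"

    if not any(present[i] for i in early_idx) and present[late_idx[0]]:
        return "late"

    if present[i0] and present[i_last] and present.sum() >= 3:
        return "zero_and_168"

    return "other"


def classify_presence_frame(
    presence: pd.DataFrame,
    time_points_h: Sequence[int] = DEFAULT_TIME_POINTS_H,
    drastic_drop_frac: float = DEFAULT_DRASTIC_DROP_FRAC,
) -> pd.Series:
    """Classify every persistent row of a genome x time frame; returns a
    Series genome -> category."""
    persistent = persistent_filter(presence)
    return pd.Series(
        {
            gid: classify_response(
                persistent.loc[gid].to_numpy(), time_points_h, drastic_drop_frac
            )
            for gid in persistent.index
        },
        dtype=object,
        name="category",
    )


def category_host_composition(
    categories: Mapping[str, str],
    host_lineages: Mapping[str, TaxonomyLineage],
) -> pd.DataFrame:
    """Count unique vOTUs per host phylum per category.

    vOTUs without a phylum-level host land in the ``unknown`` row. Column
    sums equal category sizes.
    """
    counts: Counter = Counter()
    for votu, cat in categories.items():
        lin = host_lineages.get(votu)
        phylum = lin.at_rank("phylum") if lin is not None else None
        counts[(cat, phylum or "unknown")] += 1
    if not counts:
        return pd.DataFrame(columns=list(CATEGORIES)).astype(int)
    frame = pd.Series(counts).unstack(level=0, fill_value=0)
    return frame.reindex(columns=[c for c in CATEGORIES if c in frame.columns])
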