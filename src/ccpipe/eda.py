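"""Exploratory quality control of canopy-cover time series.

Visual inspection of thousands of segmented frames does not scale. Instead,
the plot-wise canopy-cover vector of each measurement date is correlated
with that of every other date: within a growing season the ranking of plots
changes slowly, so adjacent dates should correlate strongly. A date whose
correlation with both chronological neighbours collapses is most likely a
segmentation failure (e.g. an extreme-illumination imaging day), whereas a
genuine biological shift — snow cover, snow melt — depresses a whole period
rather than a single date.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .postprocess import CCRecord

__all__ = [
    "DateFlag",
    "build_cc_matrix",
    "date_correlation_matrix",
    "flag_outlier_dates",
]


@dataclass(frozen=True)
class DateFlag:
    """A flagged measurement date with its neighbour correlations."""

    date: object
    r_prev: float | None
    r_next: float | None


def build_cc_matrix(records: list[CCRecord]) -> pd.DataFrame:
    """Arrange CC records into a plots × dates matrix.

    Dates become columns sorted ascending; combinations without a record
    are missing (NaN). Duplicate (plot, date) pairs are a data error.
    """
    if not records:
        raise ValueError("no CC records supplied")
    frame = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "date": [r.date for r in records],
            "cc": [r.cc for r in records],
        }
    )
    dup = frame.duplicated(subset=["plot_id", "date"])
    if dup.any():
        pairs = frame.loc[dup, ["plot_id", "date"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (plot, date) records: {pairs[:5]}")
    matrix = frame.pivot(index="plot_id", columns="date", values="cc")
    return matrix.sort_index(axis=1)


def date_correlation_matrix(
    m: pd.DataFrame,
    method: str = "pearson",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Correlate the plot-wise CC vectors of every pair of dates.

    Pearson's r by default (Spearman via ``method``), computed over
    pairwise-complete plots; pairs with fewer than ``min_pairs`` complete
    observations are left missing with a warning. Diagonal is 1.
    """
    if m.shape[1] < 2 or m.shape[0] < 2:
        raise ValueError("need at least 2 dates and 2 plots for correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method {method!r}")
    corr = m.corr(method=method, min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().any().any():
        warnings.warn(
            f"date pairs with fewer than {min_pairs} complete plot pairs left missing",
            RuntimeWarning,
            stacklevel=2,
        )
    return corr


def flag_outlier_dates(c: pd.DataFrame, r_min: float = 0.5) -> list[DateFlag]:
    """Flag dates whose CC correlates poorly with BOTH chronological neighbours.

    End dates have a single neighbour, which alone decides. A missing
    neighbour correlation cannot confirm an outlier, so it never triggers
    a flag. Requiring both neighbours low distinguishes one bad imaging
    day from a genuine growth change, which shifts a whole period.
    """
    dates = list(c.columns)
    if len(dates) < 3:
        warnings.warn(
            "fewer than 3 dates: insufficient context to flag outliers",
            RuntimeWarning,
            stacklevel=2,
        )
        return []
    flags: list[DateFlag] = []
    for i, date in enumerate(dates):
        r_prev = float(c.iloc[i, i - 1]) if i > 0 else None
        r_next = float(c.iloc[i, i + 1]) if i < len(dates) - 1 else None
        neighbours = [r for r in (r_prev, r_next) if r is not None]
        if not neighbours or any(np.isnan(r) for r in neighbours):
            continue
        if all(r < r_min for r in neighbours):
            flags.append(DateFlag(date=date, r_prev=r_prev, r_next=r_next))
    return flags
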