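"""The pinpoint method: boxplot statistics over fixed-width deposition bins.

An estimated critical load can be corroborated descriptively by cutting
the deposition gradient into fixed-width bins (5 kg N ha^-1 a^-1 wide by
convention, starting at 0) and comparing the response boxplots bin by
bin: the bin boundary where the response distribution first shifts
brackets the deposition level at which effects begin.  This is a screen,
not an inferential procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GradientDataset

__all__ = ["BinSummary", "ShiftRecord", "pinpoint_bins", "pinpoint_shift", "bins_to_frame"]


@dataclass
class BinSummary:
    """Tukey boxplot statistics of the response within one deposition bin.

    Bins are left-closed right-open, ``[lower_edge, upper_edge)``.
    Whiskers extend to the most extreme observation within 1.5 IQR of the
    quartiles; points beyond are listed in ``outlier_values``.  Empty bins
    have ``n_obs = 0`` and NaN statistics.
    """

    lower_edge: float
    upper_edge: float
    n_obs: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outlier_values: list[float] = field(default_factory=list)


@dataclass
class ShiftRecord:
    """Median difference between two successive non-empty bins."""

    pair: tuple[int, int]  # bin indices (into the pinpoint_bins list)
    median_difference: float
    flagged: bool


def pinpoint_bins(data: GradientDataset, bin_width: float = 5.0) -> list[BinSummary]:
    """Boxplot summaries of the response per fixed-width deposition bin.

    Bins start at 0 and are ``[k*w, (k+1)*w)``; every observation falls in
    exactly one bin (deposition is non-negative by construction).  Interior
    empty bins are reported with ``n_obs = 0``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if data.n == 0:
        raise ValueError("cannot bin an empty dataset")
    idx = np.floor(data.deposition / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    out = []
    for b in range(n_bins):
        vals = np.sort(data.response[idx == b])
        lo, hi = b * bin_width, (b + 1) * bin_width
        if vals.size == 0:
            out.append(
                BinSummary(lo, hi, 0, math.nan, math.nan, math.nan, math.nan, math.nan)
            )
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        out.append(
            BinSummary(
                lower_edge=lo,
                upper_edge=hi,
                n_obs=int(vals.size),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
                outlier_values=[float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)]],
            )
        )
    return out


def pinpoint_shift(
    bins: list[BinSummary], threshold: float | None = None
) -> list[ShiftRecord]:
    """Median differences between successive non-empty bins, with a flag.

    A pair is flagged when the response appears to have shifted: by
    default when the two bins' interquartile boxes do not overlap; with a
    numeric ``threshold``, when the absolute median difference exceeds it.
    Descriptive only — no inferential claim attaches to a flag.
    """
    occupied = [i for i, b in enumerate(bins) if b.n_obs > 0]
    if len(occupied) < 2:
        raise ValueError("need at least 2 non-empty bins")
    records = []
    for i, j in zip(occupied[:-1], occupied[1:]):
        a, b = bins[i], bins[j]
        diff = b.median - a.median
        if threshold is not None:
            flagged = abs(diff) > threshold
        else:
            flagged = (b.q1 > a.q3) or (b.q3 < a.q1)
        records.append(ShiftRecord(pair=(i, j), median_difference=float(diff), flagged=flagged))
    return records


def first_flagged(records: list[ShiftRecord]) -> ShiftRecord | None:
    """The first flagged pair, or None when nothing is flagged."""
    for r in records:
        if r.flagged:
            return r
    return None


def bins_to_frame(bins: list[BinSummary]) -> pd.DataFrame:
    """Bin summaries as a tidy table (outliers joined with ';')."""
    return pd.DataFrame(
        {
            "lower_edge": [b.lower_edge for b in bins],
            "upper_edge": [b.upper_edge for b in bins],
            "n_obs": [b.n_obs for b in bins],
            "median": [b.median for b in bins],
            "q1": [b.q1 for b in bins],
            "q3": [b.q3 for b in bins],
            "whisker_low": [b.whisker_low for b in bins],
            "whisker_high": [b.whisker_high for b in bins],
            "outliers": [";".join(f"{v:.17g}" for v in b.outlier_values) for b in bins],
        }
    )
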