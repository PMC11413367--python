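"""Cohort summary statistics with pinned quantile and rounding conventions.

Small clinical tables are summarized as median (Q1-Q3) using the exclusive
"type-6" quantile rule h = p(n+1) with linear interpolation, and percentages
as 100*count/total; all numbers are rounded half away from zero at the
precision they are reported with.  Type 6 is the convention that reproduces
both the creatinine and the albuminuria interquartile bounds of the
treatment cohort from its four printed per-patient values, so it is adopted
and pinned by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class SummaryRow:
    variable: str
    n: int
    median: float
    q1: float
    q3: float
    precision: int | tuple[int, int]


def quantile_type6(values, p: float) -> float:
    """Exclusive (type-6) sample quantile: h = p(n+1), clamped, interpolated."""
    vals = np.sort(np.asarray(values, dtype=float))
    if vals.size == 0:
        raise ValidationError("quantile of empty input")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p={p} outside [0, 1]")
    n = vals.size
    h = p * (n + 1)
    h = min(max(h, 1.0), float(n))
    lo = int(math.floor(h))
    hi = int(math.ceil(h))
    return float(vals[lo - 1] + (h - lo) * (vals[hi - 1] - vals[lo - 1]))


def round_half_away(x: float, precision: int = 0) -> float:
    """Round half away from zero at the given decimal precision."""
    factor = 10.0 ** precision
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def summarize(
    values,
    precision: int | tuple[int, int] = 1,
    variable: str = "",
) -> SummaryRow:
    """Median and type-6 IQR, rounded half away from zero.

    ``precision`` may be a single int for all three numbers, or a
    ``(median_precision, bounds_precision)`` pair for tables that print the
    bounds coarser than the median.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValidationError("summarize of empty input")
    if isinstance(precision, tuple):
        p_med, p_bounds = precision
    else:
        p_med = p_bounds = precision
    return SummaryRow(
        variable=variable,
        n=int(vals.size),
        median=round_half_away(quantile_type6(vals, 0.5), p_med),
        q1=round_half_away(quantile_type6(vals, 0.25), p_bounds),
        q3=round_half_away(quantile_type6(vals, 0.75), p_bounds),
        precision=precision,
    )


def proportion_summary(count: int, total: int, precision: int = 2) -> float:
    """Percentage 100*count/total, rounded half away from zero."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError("count must lie in [0, total]")
    return round_half_away(100.0 * count / total, precision)
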