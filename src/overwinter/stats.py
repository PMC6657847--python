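"""Trend, scenario-contrast, and latitude-equivalence statistics.

These are the inferential pieces around the projection pipeline:
ordinary linear regression of yearly winter metrics on year, two-sample
t-tests contrasting scenarios inside fixed year intervals, and the
inversion of a days-below-threshold vs. latitude regression that maps a
projected winter length to the latitude where such winters occur today.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    slope: float          # units of y per year
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def linear_trend(years, values, exclusions=()) -> TrendResult:
    """OLS regression of a yearly quantity on year.

    ``exclusions`` lists years dropped before fitting (e.g. a winter
    with unusable observational coverage).  Two-sided p for slope != 0.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values) & ~np.isin(years, np.asarray(list(exclusions), float))
    x, y = years[keep], values[keep]
    if len(x) < 3:
        raise ValueError("need at least three yearly values after exclusions")
    if np.ptp(x) == 0:
        raise ValueError("constant year values; trend undefined")
    res = sps.linregress(x, y)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2),
                       p_value=float(min(res.pvalue, 1.0)), n=len(x))


@dataclass(frozen=True)
class ContrastResult:
    interval: tuple[int, int]
    statistic: float
    df: float
    p_value: float
    n_a: int
    n_b: int
    computable: bool = True


def _as_year_map(obj) -> pd.Series:
    if isinstance(obj, pd.Series):
        return obj.astype(float)
    if isinstance(obj, dict):
        return pd.Series(obj, dtype=float)
    if isinstance(obj, pd.DataFrame):
        return obj.set_index("winter_year")["length_days"].astype(float)
    raise TypeError("expected a Series/dict keyed by winter year")


def scenario_contrast(a, b, intervals, equal_var: bool = False,
                      bonferroni: bool = False) -> list[ContrastResult]:
    """Two-sample t-tests between scenarios within fixed year intervals.

    ``a`` and ``b`` map winter year to a per-winter value (dict or
    pandas Series).  Welch's unequal-variance test is the default; set
    ``equal_var=True`` for Student's pooled variant, ``bonferroni=True``
    to correct the p-values across the intervals.  Intervals without at
    least two winters on both sides are reported as not computable
    rather than silently dropped.
    """
    sa, sb = _as_year_map(a), _as_year_map(b)
    out = []
    k = len(list(intervals))
    for (start, end) in intervals:
        va = sa[(sa.index >= start) & (sa.index <= end)].dropna().to_numpy()
        vb = sb[(sb.index >= start) & (sb.index <= end)].dropna().to_numpy()
        if len(va) < 2 or len(vb) < 2:
            out.append(ContrastResult((start, end), np.nan, np.nan, np.nan,
                                      len(va), len(vb), computable=False))
            continue
        if va.std(ddof=1) == 0.0 and vb.std(ddof=1) == 0.0:
            # degenerate: no within-group variance
            equal_means = np.isclose(va.mean(), vb.mean())
            stat = 0.0 if equal_means else np.inf * np.sign(va.mean() - vb.mean())
            p = 1.0 if equal_means else 0.0
            df = float(len(va) + len(vb) - 2)
        else:
            res = sps.ttest_ind(va, vb, equal_var=equal_var)
            stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        if bonferroni:
            p = min(1.0, p * k)
        out.append(ContrastResult((start, end), stat, df, p, len(va), len(vb)))
    return out


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([{"start": r.interval[0], "end": r.interval[1],
                          "t": r.statistic, "df": r.df, "p": r.p_value,
                          "n_a": r.n_a, "n_b": r.n_b,
                          "computable": r.computable} for r in results])


def latitude_equivalent(anchor_points, projected_days: float,
                        extrapolation_margin: float = 0.10) -> float:
    """Latitude whose present-day winters match a projected winter length.

    ``anchor_points`` is a sequence of (latitude degN, days below
    threshold) pairs from present-day stations.  Days are regressed on
    latitude by OLS and the regression is inverted at
    ``projected_days``.  Queries outside the anchors' day range (plus a
    10% margin) are refused: the inversion would extrapolate.  A slope
    that is not significantly positive triggers a warning because the
    inversion is then unreliable.
    """
    pts = np.asarray(anchor_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least three (latitude, days) anchor points")
    lats, days = pts[:, 0], pts[:, 1]
    span = days.max() - days.min()
    lo = days.min() - extrapolation_margin * span
    hi = days.max() + extrapolation_margin * span
    if not lo <= projected_days <= hi:
        raise ValueError(
            f"projected_days={projected_days} outside the anchor range "
            f"[{days.min()}, {days.max()}] ± {extrapolation_margin:.0%}")
    res = sps.linregress(lats, days)
    if res.slope <= 0 or res.pvalue > ALPHA:
        warnings.warn("days-vs-latitude slope is not significantly positive; "
                      "latitude inversion unreliable", stacklevel=2)
    return float((projected_days - res.intercept) / res.slope)
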