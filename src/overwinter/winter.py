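"""Overwintering duration, winter severity, and overwinter survival.

Blue crab (*Callinectes sapidus*) stop feeding and bury into the
sediment when water temperature falls below the critical temperature
for growth, about 9 degC.  The number of days below that threshold in a
winter is the overwintering (dormancy) duration; the mean temperature
over those days is the winter severity.  Overwinter survival follows a
Weibull accelerated-failure-time model fitted for juvenile crab, in
which temperature, salinity and body size rescale the survival time
axis:

    S(t) = exp( - t**lam * exp(-lam * (b0 + bT*Temp + bS*Sal + bZ*Size)) )

equivalently exp(-(t/eta)**lam) with eta = exp(b0 + b.x).  The shape
parameter ``lam`` and the salinity covariate come from external
sources and must be supplied explicitly — there is no defensible
default for either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import DailySeries

logger = logging.getLogger(__name__)

#: Critical temperature for growth in blue crab (degC).
DEFAULT_THRESHOLD = 9.0


def assign_winter_year(date) -> int:
    """Label a date with its winter year.

    A winter bridges two calendar years and is labelled by the first:
    the winter of 1990–1991 is winter 1990.  The winter window is
    anchored July 1 – June 30, so dates from July 1 of year y through
    June 30 of year y+1 map to winter year y.
    """
    d = pd.Timestamp(date)
    return int(d.year if d.month >= 7 else d.year - 1)


@dataclass
class WinterRecord:
    """Per-winter overwintering duration and severity."""

    winter_year: int
    length_days: int
    severity: float  # mean degC over the overwintering days; NaN when length 0
    excluded: bool = False
    threshold: float = DEFAULT_THRESHOLD
    n_days_window: int = 0

    def __post_init__(self):
        if self.length_days < 0:
            raise ValueError("length_days must be non-negative")
        if self.length_days > 0 and not np.isnan(self.severity) \
                and self.severity >= self.threshold:
            raise ValueError("severity must lie below the threshold when defined")


def winter_metrics(series: DailySeries, threshold: float = DEFAULT_THRESHOLD,
                   exclusions: tuple[int, ...] = (),
                   severity_mode: str = "below") -> list[WinterRecord]:
    """Per-winter days-below-threshold counts and mean severity.

    Only winters whose July–June window is fully covered by the series
    are emitted; partially covered winters at the series edges are
    omitted with a logged notice.  The below-threshold test is strict
    (T < threshold).  ``severity_mode`` selects whether severity
    averages only the below-threshold days (default) or the whole
    winter window (``"window"``).
    """
    if severity_mode not in ("below", "window"):
        raise ValueError("severity_mode must be 'below' or 'window'")
    s = series.complete_calendar()
    if not s.is_complete:
        raise ValueError("winter_metrics requires a complete (gap-filled) series")
    years = s.dates.year.to_numpy() - (s.dates.month.to_numpy() < 7)
    records = []
    for wy in range(int(years.min()), int(years.max()) + 1):
        w_start = pd.Timestamp(year=wy, month=7, day=1)
        w_end = pd.Timestamp(year=wy + 1, month=6, day=30)
        if s.start > w_start or s.end < w_end:
            logger.info("winter %d only partially covered; omitted", wy)
            continue
        sel = years == wy
        vals = s.values[sel]
        below = vals < threshold
        length = int(below.sum())
        if severity_mode == "below":
            severity = float(vals[below].mean()) if length else np.nan
        else:
            severity = float(vals.mean())
        records.append(WinterRecord(
            winter_year=wy, length_days=length, severity=severity,
            excluded=wy in set(exclusions), threshold=threshold,
            n_days_window=int(sel.sum())))
    return records


def winters_to_frame(records: list[WinterRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"winter_year": r.winter_year,
                          "length_days": r.length_days,
                          "severity": r.severity,
                          "excluded": r.excluded} for r in records])


@dataclass
class SurvivalParams:
    """Weibull-AFT overwinter-survival parameters for juvenile blue crab.

    The regression coefficients default to the fitted juvenile-crab
    model (intercept 3.59; 0.10 per degC; 0.02 per salinity unit; 0.03
    per mm carapace width).  ``lam`` (Weibull shape) and ``sal``
    (ambient salinity) must be supplied; ``size`` defaults to the 40 mm
    carapace width representing the juvenile stage.  ``temp`` is the
    winter-severity covariate, usually set per winter.
    """

    lam: float
    sal: float
    size: float = 40.0
    beta0: float = 3.59
    beta_temp: float = 0.10
    beta_sal: float = 0.02
    beta_size: float = 0.03
    temp: float | None = None

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("Weibull shape lam must be positive")
        if self.size <= 0:
            raise ValueError("size must be positive")

    def linear_predictor(self, temp: float | None = None) -> float:
        t = self.temp if temp is None else temp
        if t is None:
            raise ValueError("temperature covariate not set")
        return (self.beta0 + self.beta_temp * t + self.beta_sal * self.sal
                + self.beta_size * self.size)


def survival_probability(t, params: SurvivalParams, temp: float | None = None):
    """Weibull accelerated-failure-time overwinter survival S(t).

    ``t`` is the overwinter duration in days (scalar or array).
    S(0) = 1 exactly and S is strictly decreasing in t; warmer, saltier
    winters and larger crabs all raise survival at fixed duration.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("duration t must be non-negative")
    lp = params.linear_predictor(temp)
    out = np.exp(-(t ** params.lam) * np.exp(-params.lam * lp))
    return float(out) if out.ndim == 0 else out


def winter_survival_series(records: list[WinterRecord],
                           params: SurvivalParams) -> pd.DataFrame:
    """Per-winter overwinter survival from duration and severity.

    Each winter evaluates the AFT model at t = length_days with the
    winter's own severity as the temperature covariate.  Zero-length
    winters (no day below threshold, hence no overwintering) score
    survival 1.  Excluded winters carry NaN.
    """
    rows = []
    for r in records:
        if r.excluded:
            surv = np.nan
        elif r.length_days == 0:
            surv = 1.0
        else:
            surv = survival_probability(r.length_days, params, temp=r.severity)
        rows.append({"winter_year": r.winter_year, "length_days": r.length_days,
                     "severity": r.severity, "excluded": r.excluded,
                     "survival": surv})
    return pd.DataFrame(rows)
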