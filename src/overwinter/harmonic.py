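"""Harmonic climatology models and the air-to-water transfer function.

Mid-latitude estuarine temperature is well described by a linear
long-term trend plus sinusoids at the annual frequency:

    T(t) = B0 + B1*t + sum_m [ C_m cos(m*w*t) + S_m sin(m*w*t) ],
    w = 2*pi/365.25 per day.

Fitting this model to co-located air and water records yields paired
harmonic coefficients whose ratios

    cr_m = CW_m / CA_m,   sr_m = SW_m / SA_m

form a transfer function: given the harmonic structure of any air
temperature series (observed, trend-extended, or a downscaled climate
model member), the expected water temperature is

    WT(t) = B0 + B1*t + sum_m [ cr_m*CA_m cos(m*w*t) + sr_m*SA_m sin(m*w*t) ].

The estimation protocol mirrors common practice for such transfer
functions: coefficients are first estimated on a random 30% calibration
subset of days, checked by RMSE on the held-out 70%, then refit on the
full record for use in projection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .series import PREDICTED, DailySeries

#: Exact annual base angular frequency (per day).
W = 2.0 * np.pi / 365.25

#: Default origin of the continuous time coordinate.
DEFAULT_TIME_ORIGIN = pd.Timestamp("1938-01-01")

#: Harmonic coefficients with magnitude below this (degC) make ratios unreliable.
COEF_TOL = 1e-6

#: Length (years) of the trailing climatology window used to anchor
#: trend-inheriting predictions to the observed record.
CLIMATOLOGY_YEARS = 30

STAGES = ("calibration", "validation", "final")


@dataclass
class HarmonicFit:
    """OLS estimates of the trend-plus-harmonics temperature model.

    ``sds`` holds the OLS standard errors keyed ``"b0"``, ``"b1"``,
    ``"cos"`` and ``"sin"`` (the latter two are arrays over harmonics).
    ``time_mode`` is ``"continuous"`` (days since ``time_origin``; the
    default, so B1 is a genuine long-term trend) or ``"day_of_year"``
    (a degraded mode fitting seasonal climatology only).
    """

    b0: float
    b1: float
    cos_coef: np.ndarray
    sin_coef: np.ndarray
    time_origin: pd.Timestamp
    stage: str = "final"
    rmse: float = np.nan
    sds: dict | None = None
    nobs: int = 0
    data_start: pd.Timestamp | None = None
    data_end: pd.Timestamp | None = None
    variable: str = "water"
    time_mode: str = "continuous"
    w: float = W

    def __post_init__(self):
        self.cos_coef = np.atleast_1d(np.asarray(self.cos_coef, float))
        self.sin_coef = np.atleast_1d(np.asarray(self.sin_coef, float))
        if len(self.cos_coef) != len(self.sin_coef) or len(self.cos_coef) < 1:
            raise ValueError("need M >= 1 matched cosine/sine coefficient pairs")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if not np.isnan(self.rmse) and self.rmse < 0:
            raise ValueError("rmse must be non-negative")

    @property
    def M(self) -> int:
        return len(self.cos_coef)

    def time_index(self, dates) -> np.ndarray:
        """Map dates to the model's time coordinate (float days)."""
        dates = pd.DatetimeIndex(dates)
        if self.time_mode == "day_of_year":
            return (dates.dayofyear - 1).to_numpy(float)
        return ((dates - self.time_origin) / pd.Timedelta(days=1)).to_numpy(float)

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the fitted curve at (possibly fractional) day offsets ``t``."""
        t = np.asarray(t, dtype=float)
        out = self.b0 + self.b1 * t
        for m in range(1, self.M + 1):
            out = out + (self.cos_coef[m - 1] * np.cos(m * self.w * t)
                         + self.sin_coef[m - 1] * np.sin(m * self.w * t))
        return out

    def predict(self, dates) -> DailySeries:
        dates = pd.DatetimeIndex(dates)
        return DailySeries(dates, self.evaluate(self.time_index(dates)),
                           variable=self.variable, source=PREDICTED)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"b0": self.b0, "b1": self.b1,
             "cos_coef": self.cos_coef.tolist(), "sin_coef": self.sin_coef.tolist(),
             "time_origin": str(self.time_origin.date()), "stage": self.stage,
             "rmse": self.rmse, "nobs": self.nobs, "variable": self.variable,
             "time_mode": self.time_mode, "w": self.w,
             "data_start": None if self.data_start is None else str(self.data_start.date()),
             "data_end": None if self.data_end is None else str(self.data_end.date())}
        if self.sds is not None:
            d["sds"] = {"b0": self.sds["b0"], "b1": self.sds["b1"],
                        "cos": list(self.sds["cos"]), "sin": list(self.sds["sin"])}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonicFit":
        sds = d.get("sds")
        if sds is not None:
            sds = {"b0": sds["b0"], "b1": sds["b1"],
                   "cos": np.asarray(sds["cos"], float),
                   "sin": np.asarray(sds["sin"], float)}
        return cls(b0=d["b0"], b1=d["b1"], cos_coef=np.asarray(d["cos_coef"], float),
                   sin_coef=np.asarray(d["sin_coef"], float),
                   time_origin=pd.Timestamp(d["time_origin"]), stage=d["stage"],
                   rmse=d["rmse"], sds=sds, nobs=d.get("nobs", 0),
                   data_start=pd.Timestamp(d["data_start"]) if d.get("data_start") else None,
                   data_end=pd.Timestamp(d["data_end"]) if d.get("data_end") else None,
                   variable=d.get("variable", "water"),
                   time_mode=d.get("time_mode", "continuous"), w=d.get("w", W))


def fit_harmonic(series: DailySeries, M: int = 1,
                 time_origin=DEFAULT_TIME_ORIGIN, stage: str = "final",
                 time_mode: str = "continuous", cov_type: str = "hac",
                 hac_maxlags: int = 182) -> HarmonicFit:
    """Ordinary-least-squares fit of the trend-plus-harmonics model.

    Missing days are simply excluded from the design matrix.  Series
    spanning less than two full annual cycles are rejected because the
    linear trend and the annual harmonic become confounded.

    Point estimates are plain OLS.  Coefficient standard errors default
    to heteroscedasticity-and-autocorrelation-consistent (Newey–West)
    estimates with a ``hac_maxlags``-day Bartlett window, because daily
    temperature residuals are strongly autocorrelated and the classical
    OLS covariance understates the sampling error several-fold;
    ``cov_type="nonrobust"`` restores the classical covariance.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    obs = series.observed_mask
    dates = series.dates[obs]
    y = series.values[obs]
    if len(dates) < 2 * M + 3:
        raise ValueError("too few observations for the requested harmonic count")
    span = (dates[-1] - dates[0]).days
    if span < 2 * 365.25:
        raise ValueError(
            f"series spans {span} days; need at least two full annual cycles")
    time_origin = pd.Timestamp(time_origin)
    if time_mode == "day_of_year":
        t = (dates.dayofyear - 1).to_numpy(float)
    elif time_mode == "continuous":
        t = ((dates - time_origin) / pd.Timedelta(days=1)).to_numpy(float)
    else:
        raise ValueError(f"unknown time_mode {time_mode!r}")
    cols = [np.ones_like(t), t]
    for m in range(1, M + 1):
        cols.append(np.cos(m * W * t))
        cols.append(np.sin(m * W * t))
    X = np.column_stack(cols)
    model = sm.OLS(y, X)
    if cov_type == "hac":
        res = model.fit(cov_type="HAC",
                        cov_kwds={"maxlags": min(hac_maxlags, len(y) - 1)})
    elif cov_type == "nonrobust":
        res = model.fit()
    else:
        raise ValueError(f"unknown cov_type {cov_type!r}")
    p = res.params
    se = res.bse
    rmse = float(np.sqrt(np.mean(res.resid ** 2)))
    return HarmonicFit(
        b0=float(p[0]), b1=float(p[1]),
        cos_coef=p[2::2].copy(), sin_coef=p[3::2].copy(),
        time_origin=time_origin, stage=stage, rmse=rmse,
        sds={"b0": float(se[0]), "b1": float(se[1]),
             "cos": se[2::2].copy(), "sin": se[3::2].copy()},
        nobs=int(res.nobs), data_start=dates[0], data_end=dates[-1],
        variable=series.variable, time_mode=time_mode)


def calibration_split(series: DailySeries, fraction: float = 0.3,
                      seed: int | None = None) -> tuple[DailySeries, DailySeries]:
    """Random calibration/validation partition of the observed days.

    A fraction of observed days (default 30%) is drawn uniformly without
    replacement for calibration; the remainder is the validation set.
    Both outputs keep the full calendar with the unselected days marked
    missing, so each remains a valid fitting input.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    obs_idx = np.flatnonzero(series.observed_mask)
    n_obs = len(obs_idx)
    n_cal = int(round(fraction * n_obs))
    if n_cal < 1 or n_obs - n_cal < 1:
        raise ValueError("fraction leaves an empty partition")
    rng = np.random.default_rng(seed)
    cal_pos = rng.choice(obs_idx, size=n_cal, replace=False)
    cal_mask = np.zeros(len(series), dtype=bool)
    cal_mask[cal_pos] = True
    val_mask = np.zeros(len(series), dtype=bool)
    val_mask[obs_idx] = True
    val_mask[cal_pos] = False
    cal = series.select(cal_mask)
    val = series.select(val_mask)
    for part, name in ((cal, "calibration"), (val, "validation")):
        d = part.dates[part.observed_mask]
        if (d[-1] - d[0]).days < 2 * 365.25:
            raise ValueError(f"{name} partition spans under two annual cycles")
    return cal, val


@dataclass
class TransferFunction:
    """Air-to-water coefficient-ratio transfer function.

    ``water_base`` supplies the intercept/trend terms, ``air_shape`` the
    harmonic structure of the driving air record used at estimation
    time; ``cr``/``sr`` are the per-harmonic cosine/sine coefficient
    ratios and ``trend_ratio`` the water/air trend ratio.
    """

    water_base: HarmonicFit
    air_shape: HarmonicFit
    cr: np.ndarray
    sr: np.ndarray
    trend_ratio: float
    cr_sd: np.ndarray | None = None
    sr_sd: np.ndarray | None = None
    stage: str = "final"

    def __post_init__(self):
        self.cr = np.atleast_1d(np.asarray(self.cr, float))
        self.sr = np.atleast_1d(np.asarray(self.sr, float))
        if not (np.all(np.isfinite(self.cr)) and np.all(np.isfinite(self.sr))):
            raise ValueError("transfer ratios must be finite")
        if len(self.cr) != self.M or len(self.sr) != self.M:
            raise ValueError("ratio lengths must equal the harmonic count M")

    @property
    def M(self) -> int:
        return self.water_base.M

    def to_dict(self) -> dict:
        return {"water_base": self.water_base.to_dict(),
                "air_shape": self.air_shape.to_dict(),
                "cr": self.cr.tolist(), "sr": self.sr.tolist(),
                "trend_ratio": self.trend_ratio,
                "cr_sd": None if self.cr_sd is None else list(self.cr_sd),
                "sr_sd": None if self.sr_sd is None else list(self.sr_sd),
                "stage": self.stage}

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunction":
        return cls(water_base=HarmonicFit.from_dict(d["water_base"]),
                   air_shape=HarmonicFit.from_dict(d["air_shape"]),
                   cr=np.asarray(d["cr"], float), sr=np.asarray(d["sr"], float),
                   trend_ratio=d["trend_ratio"],
                   cr_sd=None if d.get("cr_sd") is None else np.asarray(d["cr_sd"], float),
                   sr_sd=None if d.get("sr_sd") is None else np.asarray(d["sr_sd"], float),
                   stage=d.get("stage", "final"))

    @classmethod
    def from_json(cls, path) -> "TransferFunction":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_transfer(air_fit: HarmonicFit, water_fit: HarmonicFit,
                   tol: float = COEF_TOL) -> TransferFunction:
    """Form per-harmonic water/air coefficient ratios from paired fits.

    Air harmonic coefficients within ``tol`` of zero are rejected
    because the corresponding ratio is undefined.  The trend ratio is
    guarded separately: a trendless air fit paired with a trendless
    water fit yields the identity ratio 1; a trendless air fit with a
    trending water fit yields NaN with a warning (trend inheritance is
    then unavailable).
    """
    if air_fit.M != water_fit.M:
        raise ValueError("air and water fits must share the harmonic count M")
    if air_fit.stage != water_fit.stage:
        raise ValueError("air and water fits must come from the same stage")
    if (np.any(np.abs(air_fit.cos_coef) < tol)
            or np.any(np.abs(air_fit.sin_coef) < tol)):
        raise ValueError("an air harmonic coefficient is within tolerance of zero; "
                         "ratio undefined")
    cr = water_fit.cos_coef / air_fit.cos_coef
    sr = water_fit.sin_coef / air_fit.sin_coef
    trend_tol = 1e-12
    if abs(air_fit.b1) < trend_tol:
        if abs(water_fit.b1) < trend_tol:
            trend_ratio = 1.0
        else:
            warnings.warn("air trend is ~0 while water trend is not; "
                          "trend_ratio set to NaN", stacklevel=2)
            trend_ratio = np.nan
    else:
        trend_ratio = float(water_fit.b1 / air_fit.b1)
    cr_sd = sr_sd = None
    if air_fit.sds is not None and water_fit.sds is not None:
        # first-order propagation, no covariance between the two fits
        cr_sd = np.abs(cr) * np.sqrt((water_fit.sds["cos"] / water_fit.cos_coef) ** 2
                                     + (air_fit.sds["cos"] / air_fit.cos_coef) ** 2)
        sr_sd = np.abs(sr) * np.sqrt((water_fit.sds["sin"] / water_fit.sin_coef) ** 2
                                     + (air_fit.sds["sin"] / air_fit.sin_coef) ** 2)
    return TransferFunction(water_base=water_fit, air_shape=air_fit,
                            cr=cr, sr=sr, trend_ratio=trend_ratio,
                            cr_sd=cr_sd, sr_sd=sr_sd, stage=air_fit.stage)


def predict_water(tf: TransferFunction, air_fit: HarmonicFit, dates,
                  mode: str = "literal",
                  junction: pd.Timestamp | None = None) -> DailySeries:
    """Predict daily water temperature from an air fit through the transfer function.

    mode="literal"
        Intercept and trend come from the water-side fit; appropriate
        when reproducing/extending the record the transfer was built on.
    mode="inherit_trend"
        The trend is ``trend_ratio * air_fit.b1`` (the driving air
        series carries its own warming, as a climate-model member does)
        and the intercept is offset so the non-seasonal part of the
        prediction matches the fitted water record at the ``junction``
        date.  The default junction is the midpoint of the trailing
        30-year climatology window of the water fit, so the prediction
        agrees with the recently observed climate on average — the
        same role bias correction plays for downscaled model output —
        while the member's own warming operates beyond it.
    """
    if air_fit.M != tf.M:
        raise ValueError("air fit and transfer function must share M")
    wb = tf.water_base
    if (air_fit.time_mode != wb.time_mode
            or air_fit.time_origin != wb.time_origin):
        raise ValueError("air fit and transfer function use different time conventions")
    dates = pd.DatetimeIndex(dates)
    if wb.time_mode == "continuous" and dates.min() < wb.time_origin:
        raise ValueError("date range predates the transfer function's time origin")
    if mode == "literal":
        b0, b1 = wb.b0, wb.b1
    elif mode == "inherit_trend":
        if not np.isfinite(tf.trend_ratio):
            raise ValueError("trend_ratio is not finite; cannot inherit trend")
        b1 = tf.trend_ratio * air_fit.b1
        if junction is not None:
            j = pd.Timestamp(junction)
        elif wb.data_end is not None:
            j = wb.data_end - pd.Timedelta(days=int(CLIMATOLOGY_YEARS * 365.25 / 2))
        else:
            raise ValueError("no junction date available for trend inheritance")
        tj = (j - wb.time_origin) / pd.Timedelta(days=1)
        b0 = wb.b0 + (wb.b1 - b1) * tj
    else:
        raise ValueError(f"unknown mode {mode!r}")
    t = ((dates - wb.time_origin) / pd.Timedelta(days=1)).to_numpy(float) \
        if wb.time_mode == "continuous" else (dates.dayofyear - 1).to_numpy(float)
    vals = b0 + b1 * t
    for m in range(1, tf.M + 1):
        vals = vals + (tf.cr[m - 1] * air_fit.cos_coef[m - 1] * np.cos(m * W * t)
                       + tf.sr[m - 1] * air_fit.sin_coef[m - 1] * np.sin(m * W * t))
    return DailySeries(dates, vals, variable="water", source=PREDICTED)


def validate_fit(fit_or_tf, holdout: DailySeries) -> float:
    """Root-mean-squared error of a fit or transfer function on held-out days.

    The caller is responsible for keeping the holdout disjoint from the
    estimation data.
    """
    obs = holdout.observed_mask
    if not obs.any():
        raise ValueError("empty holdout")
    dates = holdout.dates[obs]
    y = holdout.values[obs]
    if isinstance(fit_or_tf, TransferFunction):
        pred = predict_water(fit_or_tf, fit_or_tf.air_shape, dates).values
    elif isinstance(fit_or_tf, HarmonicFit):
        pred = fit_or_tf.evaluate(fit_or_tf.time_index(dates))
    else:
        raise TypeError("expected a HarmonicFit or TransferFunction")
    return float(np.sqrt(np.mean((pred - y) ** 2)))
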