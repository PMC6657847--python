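"""Daily water-temperature projections to 2100 with ensemble uncertainty.

Two projection scenarios are supported:

``extended_trend``
    The fitted transfer function's least-squares point estimates are
    evaluated directly beyond the observational record, extending the
    observed warming trend.  Uncertainty comes from resampling the
    regression coefficients from their estimated sampling distributions.

``downscaled_gcm``
    An ensemble of daily air-temperature members (e.g. statistically
    downscaled global climate model runs under a high-emissions
    pathway) drives the transfer function; each member is refit with
    the harmonic model and converted to water temperature, and the
    ensemble is summarised by a per-day mean and standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonic import HarmonicFit, TransferFunction, fit_harmonic, predict_water
from .series import PREDICTED, DailySeries

logger = logging.getLogger(__name__)

#: Members missing more than this fraction of days are rejected.
MAX_MEMBER_MISSING = 0.05


@dataclass
class ProjectionEnsemble:
    """A set of projected water members with per-day mean and spread."""

    members: list[DailySeries]
    daily_mean: DailySeries
    daily_sd: DailySeries
    scenario: str

    @property
    def n_members(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.daily_mean.dates,
                             "mean": self.daily_mean.values,
                             "sd": self.daily_sd.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, date_format="%Y-%m-%d")


def _summarize(members: list[DailySeries], scenario: str) -> ProjectionEnsemble:
    dates = members[0].dates
    for m in members[1:]:
        if len(m.dates) != len(dates) or (m.dates != dates).any():
            raise ValueError("ensemble members must share one date range")
    mat = np.vstack([m.values for m in members])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(members) > 1 else np.zeros(len(dates))
    return ProjectionEnsemble(
        members=members,
        daily_mean=DailySeries(dates, mean, variable="water", source=PREDICTED),
        daily_sd=DailySeries(dates, sd, variable="water", source=PREDICTED),
        scenario=scenario)


def extend_trend(tf: TransferFunction, end_date,
                 start_date=None) -> DailySeries:
    """Evaluate the point-estimate projection from the end of observations.

    Runs from the day after the last fitted water observation (or
    ``start_date``) through ``end_date`` using the literal transfer
    prediction, i.e. the observed trend extended.
    """
    end_date = pd.Timestamp(end_date)
    if start_date is None:
        if tf.water_base.data_end is None:
            raise ValueError("transfer function carries no data end date; "
                             "pass start_date explicitly")
        start_date = tf.water_base.data_end + pd.Timedelta(days=1)
    start_date = pd.Timestamp(start_date)
    if end_date < start_date:
        raise ValueError("end_date precedes the end of observations")
    dates = pd.date_range(start_date, end_date, freq="D")
    return predict_water(tf, tf.air_shape, dates, mode="literal")


def resample_projections(tf: TransferFunction, n: int, seed: int,
                         end_date, start_date=None) -> ProjectionEnsemble:
    """Propagate coefficient uncertainty by resampling the regression parameters.

    Each member redraws every coefficient independently from
    Normal(estimate, SD) — the water intercept and trend, the air
    harmonic coefficients, and the transfer ratios — then evaluates the
    projection.  Ignoring the coefficient covariances understates the
    joint uncertainty slightly; see the methods note.
    """
    if n < 2:
        raise ValueError("need at least two resampled members")
    wb, af = tf.water_base, tf.air_shape
    if wb.sds is None or af.sds is None or tf.cr_sd is None or tf.sr_sd is None:
        raise ValueError("transfer function lacks coefficient standard errors")
    base = extend_trend(tf, end_date, start_date)
    t = ((base.dates - wb.time_origin) / pd.Timedelta(days=1)).to_numpy(float)
    rng = np.random.default_rng(seed)
    cosines = np.stack([np.cos(m * wb.w * t) for m in range(1, tf.M + 1)])
    sines = np.stack([np.sin(m * wb.w * t) for m in range(1, tf.M + 1)])
    members = []
    for _ in range(n):
        b0 = rng.normal(wb.b0, wb.sds["b0"])
        b1 = rng.normal(wb.b1, wb.sds["b1"])
        ca = rng.normal(af.cos_coef, af.sds["cos"])
        sa = rng.normal(af.sin_coef, af.sds["sin"])
        cr = rng.normal(tf.cr, tf.cr_sd)
        sr = rng.normal(tf.sr, tf.sr_sd)
        vals = b0 + b1 * t + (cr * ca) @ cosines + (sr * sa) @ sines
        members.append(DailySeries(base.dates, vals, variable="water",
                                   source=PREDICTED))
    return _summarize(members, "extended_trend")


def read_member_ensemble(source, layout: dict) -> list[DailySeries]:
    """Read an ensemble of daily min/max air-temperature members.

    ``source`` is a wide CSV path (or an already-loaded DataFrame): one
    date column plus one min and one max column per member-cell.  The
    ``layout`` mapping declares the columns::

        {"date": "date",
         "members": {"member01": [["m01_c1_min", "m01_c1_max"], ...], ...}}

    Per member and day the value is the mean over grid cells of the
    (min+max)/2 midpoint.  Days where min exceeds max are rejected with
    a logged warning; members missing more than 5% of days are dropped.
    A NetCDF path (variables/dims named in ``layout`` as ``min_var``,
    ``max_var``, ``time_dim``, ``member_dim``, ``cell_dim``) is also
    accepted and reshaped to the same wide layout.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        p = Path(source)
        if p.suffix in (".nc", ".cdf", ".netcdf"):
            df, layout = _netcdf_to_wide(p, layout)
        else:
            df = pd.read_csv(p)
    dates = pd.to_datetime(df[layout.get("date", "date")])
    out = []
    for name, cells in layout["members"].items():
        mids = []
        for mincol, maxcol in cells:
            mn = df[mincol].to_numpy(float)
            mx = df[maxcol].to_numpy(float)
            bad = mn > mx
            if bad.any():
                logger.warning("member %s: %d day(s) with min > max rejected",
                               name, int(bad.sum()))
                mn = np.where(bad, np.nan, mn)
                mx = np.where(bad, np.nan, mx)
            mids.append((mn + mx) / 2.0)
        with np.errstate(invalid="ignore"):
            stack = np.vstack(mids)
            counts = np.sum(~np.isnan(stack), axis=0)
            mid = np.where(counts > 0, np.nansum(stack, axis=0) / np.maximum(counts, 1),
                           np.nan)
        frac_missing = float(np.isnan(mid).mean())
        if frac_missing > MAX_MEMBER_MISSING:
            logger.warning("member %s rejected: %.1f%% of days missing",
                           name, 100 * frac_missing)
            continue
        out.append(DailySeries(dates, mid, variable="air", source=name))
    if not out:
        raise ValueError("no usable ensemble members")
    return out


def _netcdf_to_wide(path: Path, layout: dict) -> tuple[pd.DataFrame, dict]:
    import xarray as xr

    ds = xr.open_dataset(path)
    tdim = layout.get("time_dim", "time")
    mdim = layout.get("member_dim", "member")
    cdim = layout.get("cell_dim", "cell")
    mn = ds[layout.get("min_var", "tasmin")]
    mx = ds[layout.get("max_var", "tasmax")]
    df = pd.DataFrame({"date": pd.to_datetime(ds[tdim].values)})
    members: dict[str, list[list[str]]] = {}
    for mi, mem in enumerate(ds[mdim].values):
        name = str(mem)
        cells = []
        for ci in range(ds.sizes[cdim]):
            cmin = f"{name}_c{ci}_min"
            cmax = f"{name}_c{ci}_max"
            df[cmin] = mn.isel({mdim: mi, cdim: ci}).values
            df[cmax] = mx.isel({mdim: mi, cdim: ci}).values
            cells.append([cmin, cmax])
        members[name] = cells
    return df, {"date": "date", "members": members}


def project_ensemble(tf: TransferFunction, air_members: list[DailySeries],
                     start_date=None, end_date=None,
                     refit_window_years: int | None = None,
                     mode: str = "inherit_trend") -> ProjectionEnsemble:
    """Drive the transfer function with each air member and summarise.

    Each member's air record is refit with the harmonic model (whole
    span by default; ``refit_window_years`` switches to consecutive
    fixed-length windows so curvature in the member's warming is
    tracked piecewise) and converted to water temperature.  Overlap
    with the observational era is used for fitting but reported
    projections start the day after the fitted water record ends
    unless ``start_date`` says otherwise.
    """
    if not air_members:
        raise ValueError("empty member list")
    wb = tf.water_base
    if start_date is None:
        if wb.data_end is None:
            raise ValueError("transfer function carries no data end date")
        start_date = wb.data_end + pd.Timedelta(days=1)
    start_date = pd.Timestamp(start_date)
    end = min(m.end for m in air_members)
    if end_date is not None:
        end = min(end, pd.Timestamp(end_date))
    dates = pd.date_range(start_date, end, freq="D")
    if len(dates) == 0:
        raise ValueError("empty projection range")
    water_members = []
    for mem in air_members:
        filled = mem if mem.is_complete else _fill_member(mem)
        if refit_window_years is None:
            fit = fit_harmonic(filled, M=tf.M, time_origin=wb.time_origin,
                               stage="final", time_mode=wb.time_mode)
            pred = predict_water(tf, fit, dates, mode=mode)
        else:
            pred = _blockwise_predict(tf, filled, dates, refit_window_years, mode)
        water_members.append(pred)
    return _summarize(water_members, "downscaled_gcm")


def _fill_member(member: DailySeries) -> DailySeries:
    from .series import interpolate_gaps
    return interpolate_gaps(member)


def _blockwise_predict(tf: TransferFunction, member: DailySeries,
                       dates: pd.DatetimeIndex, window_years: int,
                       mode: str) -> DailySeries:
    """Refit the member per consecutive window and predict its own days."""
    span_days = int(round(window_years * 365.25))
    vals = np.full(len(dates), np.nan)
    block_start = dates[0]
    while block_start <= dates[-1]:
        block_end = min(block_start + pd.Timedelta(days=span_days - 1), dates[-1])
        # fit on the member window centred on the block, clipped to the record
        fit_start = max(member.start, block_start - pd.Timedelta(days=span_days // 2))
        fit_end = min(member.end, block_end + pd.Timedelta(days=span_days // 2))
        fit = fit_harmonic(member.window(fit_start, fit_end), M=tf.M,
                           time_origin=tf.water_base.time_origin,
                           stage="final", time_mode=tf.water_base.time_mode)
        sel = (dates >= block_start) & (dates <= block_end)
        vals[sel] = predict_water(tf, fit, dates[sel], mode=mode).values
        block_start = block_end + pd.Timedelta(days=1)
    return DailySeries(dates, vals, variable="water", source=PREDICTED)
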