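"""Daily temperature series: containers, source merging, gap filling, persistence.

The long pier records this package was designed around are once-daily
air and water temperatures with frequent short gaps (weekends, holidays)
and occasional multi-week outages, patched from nearby buoy and
monitoring-program stations.  :class:`DailySeries` keeps a per-day
provenance tag alongside the values so that every downstream number can
be traced to an observing source, an interpolated fill, or a model
prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "missing"
INTERPOLATED = "interpolated"
PREDICTED = "predicted"
VARIABLES = ("air", "water")

#: Autocorrelation reference level for the decorrelation scale (e-folding).
EFOLD = 1.0 / np.e


class DailySeries:
    """A date-indexed daily temperature record with per-day provenance.

    Parameters
    ----------
    dates : array-like of datetime
        Calendar dates.  Must be unique; they are sorted on construction.
        Gaps in the calendar are allowed and are equivalent to missing
        days (use :meth:`complete_calendar` to materialise them).
    values : array-like of float
        Temperatures in degrees Celsius; NaN marks a missing day.
    provenance : array-like of str, optional
        One tag per day naming the observing source, or one of
        ``"interpolated"``, ``"predicted"``, ``"missing"``.  Defaults to
        ``source`` where a value is present and ``"missing"`` elsewhere.
    variable : {"air", "water"}
        Which medium the series measures.
    source : str
        Default provenance tag for observed days when ``provenance`` is
        not given.
    """

    def __init__(self, dates, values, provenance=None, variable="water",
                 source="observed"):
        if variable not in VARIABLES:
            raise ValueError(f"variable must be one of {VARIABLES}, got {variable!r}")
        dates = pd.DatetimeIndex(dates)
        if dates.has_duplicates:
            raise ValueError("duplicate dates within one source")
        values = np.asarray(values, dtype=float)
        if len(values) != len(dates):
            raise ValueError("dates and values length mismatch")
        if not dates.is_monotonic_increasing:
            order = np.argsort(dates)
            dates = dates[order]
            values = values[order]
            if provenance is not None:
                provenance = np.asarray(provenance, dtype=object)[order]
        nan = np.isnan(values)
        if provenance is None:
            provenance = np.where(nan, MISSING, source).astype(object)
        else:
            provenance = np.asarray(provenance, dtype=object).copy()
            if len(provenance) != len(dates):
                raise ValueError("provenance length mismatch")
            provenance[nan] = MISSING
            if np.any(~nan & (provenance == MISSING)):
                raise ValueError("non-missing value tagged 'missing'")
        self.dates = dates.normalize()
        self.values = values
        self.provenance = provenance
        self.variable = variable

    # -- basic introspection -------------------------------------------------

    def __len__(self):
        return len(self.dates)

    def __repr__(self):
        return (f"DailySeries({self.variable}, {self.start.date()}–{self.end.date()}, "
                f"{self.observed_mask.sum()}/{len(self)} observed)")

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean mask of days carrying a value (observed, filled or predicted)."""
        return ~np.isnan(self.values)

    @property
    def is_contiguous(self) -> bool:
        """True when every calendar day between start and end is present."""
        return len(self) == (self.end - self.start).days + 1

    @property
    def is_complete(self) -> bool:
        """True when contiguous and free of missing values."""
        return self.is_contiguous and bool(self.observed_mask.all())

    def copy(self) -> "DailySeries":
        return DailySeries(self.dates, self.values.copy(),
                           self.provenance.copy(), self.variable)

    def complete_calendar(self) -> "DailySeries":
        """Reindex onto the full daily calendar between start and end.

        Days absent from the index become explicit missing days.
        """
        if self.is_contiguous:
            return self.copy()
        idx = pd.date_range(self.start, self.end, freq="D")
        vals = np.full(len(idx), np.nan)
        prov = np.array([MISSING] * len(idx), dtype=object)
        pos = idx.get_indexer(self.dates)
        vals[pos] = self.values
        prov[pos] = self.provenance
        return DailySeries(idx, vals, prov, self.variable)

    def select(self, mask) -> "DailySeries":
        """Return a copy with values outside ``mask`` set missing (same calendar)."""
        vals = np.where(mask, self.values, np.nan)
        prov = np.where(mask, self.provenance, MISSING).astype(object)
        return DailySeries(self.dates, vals, prov, self.variable)

    def window(self, start, end) -> "DailySeries":
        """Restrict to dates in the closed interval [start, end]."""
        keep = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        return DailySeries(self.dates[keep], self.values[keep],
                           self.provenance[keep], self.variable)

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "value": self.values,
                             "provenance": self.provenance})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, path, variable, date_col="date", value_col="value",
                 provenance_col="provenance", source=None) -> "DailySeries":
        """Read a one-row-per-day CSV.

        ``source`` names the observing platform when the file has no
        provenance column (e.g. a single-station export).
        """
        df = pd.read_csv(path)
        if provenance_col in df.columns:
            prov = df[provenance_col].to_numpy(dtype=object)
        else:
            prov = None
        return cls(pd.to_datetime(df[date_col]), df[value_col].to_numpy(float),
                   prov, variable, source=source or "observed")


def table_to_sources(frame: pd.DataFrame, variable: str, columns: dict,
                     date_col: str = "Date") -> list[DailySeries]:
    """Split a wide multi-station table into per-source :class:`DailySeries`.

    ``columns`` maps source name -> column header, in priority order
    (first entry is the primary station).  This adapts arbitrary headers,
    e.g. the published pier dataset whose columns are named like
    ``"CBL Water Temp (degC)"``.
    """
    dates = pd.to_datetime(frame[date_col])
    out = []
    for name, col in columns.items():
        out.append(DailySeries(dates, frame[col].to_numpy(float),
                               variable=variable, source=name))
    return out


@dataclass(frozen=True)
class GapSummary:
    """Run-length statistics of the missing interior days of a raw record."""

    mean_gap_length: float
    max_gap_length: int
    filled_fraction: float
    n_gaps: int

    def __post_init__(self):
        if self.mean_gap_length > self.max_gap_length:
            raise ValueError("mean gap length exceeds max gap length")
        if not 0.0 <= self.filled_fraction <= 1.0:
            raise ValueError("filled_fraction outside [0, 1]")

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start index, length) of each maximal run of True in ``mask``."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def merge_sources(primary: DailySeries, fallbacks: list[DailySeries]) -> DailySeries:
    """Combine a primary station with fallback stations in priority order.

    Each day takes the primary value when present, otherwise the first
    fallback carrying a value; the winning source's provenance tag is
    kept.  Days with no value anywhere stay missing.
    """
    sources = [primary, *fallbacks]
    variables = {s.variable for s in sources}
    if len(variables) > 1:
        raise ValueError(f"mixed variable types in merge: {sorted(variables)}")
    start = min(s.start for s in sources)
    end = max(s.end for s in sources)
    idx = pd.date_range(start, end, freq="D")
    vals = np.full(len(idx), np.nan)
    prov = np.array([MISSING] * len(idx), dtype=object)
    # lowest priority written first, higher priorities overwrite
    for s in reversed(sources):
        pos = idx.get_indexer(s.dates)
        obs = s.observed_mask
        vals[pos[obs]] = s.values[obs]
        prov[pos[obs]] = s.provenance[obs]
    return DailySeries(idx, vals, prov, primary.variable)


def interpolate_gaps(series: DailySeries, max_gap: int | None = None) -> DailySeries:
    """Fill interior missing runs by linear interpolation.

    Straight-line filling is defensible for estuarine water temperature
    because the high specific heat of water keeps day-to-day changes
    small relative to the seasonal cycle.  Leading/trailing missing runs
    are trimmed, never extrapolated.  Runs longer than ``max_gap`` days
    are left missing and logged (default: no limit).
    """
    s = series.complete_calendar()
    obs = s.observed_mask
    if obs.sum() < 2:
        raise ValueError("need at least two observed values to interpolate")
    first, last = np.flatnonzero(obs)[[0, -1]]
    dates = s.dates[first:last + 1]
    vals = s.values[first:last + 1].copy()
    prov = s.provenance[first:last + 1].copy()
    miss = np.isnan(vals)
    filled = pd.Series(vals).interpolate(method="linear").to_numpy()
    for start_i, length in _missing_runs(miss):
        if max_gap is not None and length > max_gap:
            logger.warning("gap of %d days starting %s exceeds max_gap=%d; left missing",
                           length, dates[start_i].date(), max_gap)
            filled[start_i:start_i + length] = np.nan
        else:
            prov[start_i:start_i + length] = INTERPOLATED
    return DailySeries(dates, filled, prov, s.variable)


def gap_statistics(series: DailySeries) -> GapSummary:
    """Summarise the interior missing runs of a raw (unfilled) record."""
    s = series.complete_calendar()
    obs = s.observed_mask
    if not obs.any():
        raise ValueError("all-missing series")
    first, last = np.flatnonzero(obs)[[0, -1]]
    miss = ~obs[first:last + 1]
    total = last - first + 1
    runs = _missing_runs(miss)
    if not runs:
        return GapSummary(0.0, 0, 0.0, 0)
    lengths = np.array([r[1] for r in runs])
    return GapSummary(float(lengths.mean()), int(lengths.max()),
                      float(lengths.sum() / total), len(runs))


def decorrelation_scale(series: DailySeries, deseasonalize: bool = False,
                        max_lag: int | None = None) -> int:
    """Smallest positive lag at which the sample autocorrelation drops below 1/e.

    A measure of temporal persistence of the daily record.  By default
    the autocorrelation is computed on the mean-removed series with the
    seasonal cycle left in; ``deseasonalize=True`` removes a fitted
    trend-plus-annual-harmonic model first, so the scale describes the
    persistence of the day-to-day anomalies instead.
    """
    from statsmodels.tsa.stattools import acf

    s = series.complete_calendar()
    if not s.is_complete:
        raise ValueError("decorrelation_scale requires a gap-filled series")
    n = len(s)
    if (s.end - s.start).days < 730:
        raise ValueError("series shorter than two years")
    x = s.values.astype(float)
    if deseasonalize:
        from .harmonic import fit_harmonic
        fit = fit_harmonic(s, M=1, time_origin=s.start)
        x = x - fit.evaluate(fit.time_index(s.dates))
    nlags = max_lag if max_lag is not None else min(n - 2, 1500)
    rho = acf(x - x.mean(), nlags=nlags, fft=True)
    below = np.flatnonzero(rho[1:] < EFOLD)
    if below.size == 0:
        raise ValueError(
            f"autocorrelation stayed above 1/e out to lag {nlags}; series too short "
            "for its persistence")
    return int(below[0] + 1)
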