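"""Synthetic daily air/water temperature records with known ground truth.

The generator emulates the statistical structure of a long mid-Chesapeake
pier record (1938–2016): a slow linear warming trend, an annual harmonic
cycle, strongly persistent AR(1) day-to-day anomalies correlated between
air and water, and a missing-data pattern of probabilistic weekend and
holiday gaps plus occasional multi-week outages patched by fallback
stations.  Every generating parameter is retained in a truth record so
each pipeline stage can be tested against a closed form.

Default regime (see the methods note for the derivations):

* water reference-window (1961–1990) mean 15.2 degC, warming
  0.022 degC/yr, annual amplitude 12.3 degC (total daily SD ~8.9 degC),
* AR(1) water anomalies with e-folding time 91 days and marginal SD
  1.5 degC,
* ~13–15% of days missing in the raw single-station record,
* winter (days < 9 degC) lengths roughly 90–150 days, declining with
  the trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .harmonic import W
from .series import DailySeries

#: Column layout of the wide multi-station observation table.
S1_AIR_COLUMNS = {"CBL": "CBL Air Temp (degC)",
                  "NOAA Solomons": "NOAA Solomons Air Temp (degC)",
                  "NOAA CovePt": "NOAA CovePt Air Temp (degC)"}
S1_WATER_COLUMNS = {"CBL": "CBL Water Temp (degC)",
                    "NOAA Solomons": "NOAA Solomons Water Temp (degC)",
                    "CBP": "CBP Water Temp (degC)"}


@dataclass
class ClimateSimConfig:
    """Parameters of the synthetic air/water climate generator.

    Temperatures in degC, trends in degC per year, amplitudes as the
    half peak-to-trough range of the annual cycle, peak days as day of
    year of the seasonal maximum.  Noise SDs are marginal (stationary)
    standard deviations of the AR(1) anomaly processes; ``noise_corr``
    correlates the air and water innovations.  Gap parameters control
    the injected missingness of the raw single-station record.
    """

    start: str = "1938-01-01"
    end: str = "2016-12-31"
    time_origin: str = "1938-01-01"
    ref_start: str = "1961-01-01"
    ref_end: str = "1990-12-31"
    # deterministic structure
    air_mean_ref: float = 14.6
    water_mean_ref: float = 15.2
    trend_c_per_year: float = 0.022
    trend_ratio: float = 1.0
    air_amplitude: float = 14.5
    air_peak_doy: float = 200.0
    water_amplitude: float = 12.3
    water_peak_doy: float = 210.0
    # AR(1) anomalies
    air_phi: float = 0.95
    air_sd: float = 2.5
    water_phi: float = float(np.exp(-1.0 / 91.0))
    water_sd: float = 1.5
    noise_corr: float = 0.6
    # gap model
    weekend_prob: float = 0.35
    holiday_frac: float = 0.01
    long_gap_rate_per_year: float = 1.5
    long_gap_mean_days: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("air_phi", "water_phi"):
            if not abs(getattr(self, name)) < 1.0:
                raise ValueError(f"{name} must satisfy |phi| < 1")
        for name in ("air_sd", "water_sd", "air_amplitude", "water_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("weekend_prob", "holiday_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.noise_corr <= 1.0:
            raise ValueError("noise_corr must lie in [-1, 1]")

    # -- derived deterministic coefficients ---------------------------------

    @property
    def origin(self) -> pd.Timestamp:
        return pd.Timestamp(self.time_origin)

    @property
    def trend_per_day(self) -> float:
        return self.trend_c_per_year / 365.25

    def _ref_mid_t(self) -> float:
        mid = pd.Timestamp(self.ref_start) + (pd.Timestamp(self.ref_end)
                                              - pd.Timestamp(self.ref_start)) / 2
        return (mid - self.origin) / pd.Timedelta(days=1)

    @property
    def air_b0(self) -> float:
        return self.air_mean_ref - self.trend_per_day * self._ref_mid_t()

    @property
    def water_offset(self) -> float:
        return self.water_mean_ref - self.trend_ratio * self.trend_per_day \
            * self._ref_mid_t()

    @staticmethod
    def _harmonic_pair(amplitude: float, peak_doy: float) -> tuple[float, float]:
        phase = W * (peak_doy - 1.0)
        return amplitude * np.cos(phase), amplitude * np.sin(phase)

    @property
    def air_cos(self) -> np.ndarray:
        return np.array([self._harmonic_pair(self.air_amplitude, self.air_peak_doy)[0]])

    @property
    def air_sin(self) -> np.ndarray:
        return np.array([self._harmonic_pair(self.air_amplitude, self.air_peak_doy)[1]])

    @property
    def cr(self) -> np.ndarray:
        ca, _ = self._harmonic_pair(self.air_amplitude, self.air_peak_doy)
        cw, _ = self._harmonic_pair(self.water_amplitude, self.water_peak_doy)
        return np.array([cw / ca])

    @property
    def sr(self) -> np.ndarray:
        _, sa = self._harmonic_pair(self.air_amplitude, self.air_peak_doy)
        _, sw = self._harmonic_pair(self.water_amplitude, self.water_peak_doy)
        return np.array([sw / sa])

    # -- closed-form deterministic curves ------------------------------------

    def t_index(self, dates) -> np.ndarray:
        return ((pd.DatetimeIndex(dates) - self.origin)
                / pd.Timedelta(days=1)).to_numpy(float)

    def deterministic_air(self, dates) -> np.ndarray:
        t = self.t_index(dates)
        return (self.air_b0 + self.trend_per_day * t
                + self.air_cos[0] * np.cos(W * t) + self.air_sin[0] * np.sin(W * t))

    def deterministic_water(self, dates) -> np.ndarray:
        # cw = cr*ca and sw = sr*sa by construction; using the water pair
        # directly stays defined when the air amplitude is zero
        t = self.t_index(dates)
        cw, sw = self._harmonic_pair(self.water_amplitude, self.water_peak_doy)
        return (self.water_offset + self.trend_ratio * self.trend_per_day * t
                + cw * np.cos(W * t) + sw * np.sin(W * t))

    def expected_window_mean(self, variable: str, start, end) -> float:
        """Mean of the noiseless curve over a date window (truth oracle)."""
        dates = pd.date_range(start, end, freq="D")
        curve = (self.deterministic_air(dates) if variable == "air"
                 else self.deterministic_water(dates))
        return float(curve.mean())

    def expected_winter_length(self, winter_year: int,
                               threshold: float = 9.0) -> int:
        """Days below threshold in a winter of the noiseless water curve."""
        dates = pd.date_range(pd.Timestamp(year=winter_year, month=7, day=1),
                              pd.Timestamp(year=winter_year + 1, month=6, day=30),
                              freq="D")
        return int((self.deterministic_water(dates) < threshold).sum())

    @classmethod
    def from_yaml(cls, path) -> "ClimateSimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Ground truth accompanying one generated air/water pair."""

    config: ClimateSimConfig
    air: DailySeries          # complete noisy series, no gaps
    water: DailySeries
    air_det: np.ndarray       # noiseless curves on the same dates
    water_det: np.ndarray


def _ar1(rng_innov: np.ndarray, phi: float, marginal_sd: float) -> np.ndarray:
    """Stationary AR(1) path from standard-normal innovations."""
    # callers pass a burn-in so the zero initial state washes out
    innov_sd = marginal_sd * np.sqrt(1.0 - phi ** 2)
    return lfilter([1.0], [1.0, -phi], innov_sd * rng_innov)


def _correlated_noise(rng: np.random.Generator, n: int,
                      cfg: ClimateSimConfig) -> tuple[np.ndarray, np.ndarray]:
    burn = 1000
    z = rng.standard_normal((2, n + burn))
    rho = cfg.noise_corr
    za = z[0]
    zw = rho * z[0] + np.sqrt(1.0 - rho ** 2) * z[1]
    na = _ar1(za, cfg.air_phi, cfg.air_sd)[burn:]
    nw = _ar1(zw, cfg.water_phi, cfg.water_sd)[burn:]
    return na, nw


def _inject_gaps(rng: np.random.Generator, dates: pd.DatetimeIndex,
                 cfg: ClimateSimConfig) -> np.ndarray:
    n = len(dates)
    miss = np.zeros(n, dtype=bool)
    weekend = dates.dayofweek.to_numpy() >= 5
    miss |= weekend & (rng.random(n) < cfg.weekend_prob)
    miss |= rng.random(n) < cfg.holiday_frac
    years = n / 365.25
    for _ in range(rng.poisson(cfg.long_gap_rate_per_year * years)):
        start = rng.integers(0, n)
        length = rng.geometric(1.0 / cfg.long_gap_mean_days)
        miss[start:start + length] = True
    # keep the record endpoints observed so the span is well defined
    miss[0] = miss[-1] = False
    return miss


def generate_pair(config: ClimateSimConfig,
                  with_gaps: bool = True) -> tuple[DailySeries, DailySeries, SimTruth]:
    """Generate one air/water pair: raw (gapped) series plus ground truth.

    The same seed always yields the same output.  ``with_gaps=False``
    returns the complete series as the raw ones.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, config.end, freq="D")
    n = len(dates)
    air_det = config.deterministic_air(dates)
    water_det = config.deterministic_water(dates)
    if config.air_sd > 0 or config.water_sd > 0:
        na, nw = _correlated_noise(rng, n, config)
    else:
        na = nw = np.zeros(n)
    air_full = air_det + na
    water_full = water_det + nw
    truth = SimTruth(config=config,
                     air=DailySeries(dates, air_full, variable="air", source="truth"),
                     water=DailySeries(dates, water_full, variable="water",
                                       source="truth"),
                     air_det=air_det, water_det=water_det)
    if with_gaps:
        air_miss = _inject_gaps(rng, dates, config)
        water_miss = _inject_gaps(rng, dates, config)
    else:
        air_miss = water_miss = np.zeros(n, dtype=bool)
    air_raw = DailySeries(dates, np.where(air_miss, np.nan, air_full),
                          variable="air", source="CBL")
    water_raw = DailySeries(dates, np.where(water_miss, np.nan, water_full),
                            variable="water", source="CBL")
    return air_raw, water_raw, truth


def generate_observation_table(config: ClimateSimConfig,
                               fallback_coverage: tuple[float, float] = (0.5, 0.35),
                               fallback_sd: float = 0.25
                               ) -> tuple[pd.DataFrame, SimTruth]:
    """Emit a wide multi-station table in the published pier-dataset layout.

    The primary (CBL) columns carry the gapped raw record; two fallback
    stations per variable observe independent random subsets of days
    (``fallback_coverage`` fractions) with small instrument scatter
    ``fallback_sd`` around the true series, mimicking nearby buoy and
    monitoring-program stations.
    """
    air_raw, water_raw, truth = generate_pair(config)
    rng = np.random.default_rng(config.seed + 1)
    dates = truth.air.dates
    n = len(dates)
    frame = pd.DataFrame({"Date": dates})

    def fallback(full_vals: np.ndarray, coverage: float) -> np.ndarray:
        seen = rng.random(n) < coverage
        vals = full_vals + rng.normal(0.0, fallback_sd, n)
        return np.where(seen, vals, np.nan)

    frame[S1_AIR_COLUMNS["CBL"]] = air_raw.values
    frame[S1_WATER_COLUMNS["CBL"]] = water_raw.values
    for (name, col), cov in zip(list(S1_AIR_COLUMNS.items())[1:], fallback_coverage):
        frame[col] = fallback(truth.air.values, cov)
    for (name, col), cov in zip(list(S1_WATER_COLUMNS.items())[1:], fallback_coverage):
        frame[col] = fallback(truth.water.values, cov)
    return frame, truth


def generate_member_ensemble(config: ClimateSimConfig, n_members: int = 41,
                             member_trend_per_century: float = 4.1,
                             trend_spread_per_century: float = 1.0,
                             start: str = "1950-01-01", end: str = "2099-12-31",
                             n_cells: int = 3, diurnal_range: float = 8.0,
                             cell_sd: float = 0.2, seed: int | None = None,
                             out_dir=None) -> tuple[pd.DataFrame, dict, np.ndarray]:
    """Generate a downscaled-GCM-like ensemble of daily min/max air members.

    Members share the observational seasonal structure, are anchored to
    the observed air climatology at the reference-window midpoint, and
    differ in a warming rate drawn from Normal(``member_trend_per_century``,
    ``trend_spread_per_century``) degC/century plus independent AR(1)
    noise.  The default warming rate (4.1 degC/century) is the value
    that carries the reference-window water climatology to the
    high-emissions end-of-century mean through the transfer pipeline's
    trailing-climatology anchoring; see the methods note.  Each member reports ``n_cells`` grid cells of daily min/max
    (midpoint = member value +/- cell scatter), the exact layout the
    ensemble reader consumes.  Returns (wide frame, layout mapping,
    true member trends in degC/century); optionally writes
    ``ensemble.csv`` and ``layout.yaml`` to ``out_dir``.
    """
    if n_members < 2:
        raise ValueError("need at least two ensemble members")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dates = pd.date_range(start, end, freq="D")
    t = config.t_index(dates)
    t_anchor = config._ref_mid_t()
    trends = rng.normal(member_trend_per_century, trend_spread_per_century,
                        n_members)  # degC/century
    seasonal = (config.air_cos[0] * np.cos(W * t)
                + config.air_sin[0] * np.sin(W * t))
    columns: dict = {"date": dates}
    layout: dict = {"date": "date", "members": {}}
    half = diurnal_range / 2.0
    n = len(dates)
    for i in range(n_members):
        b1 = trends[i] / 100.0 / 365.25
        b0 = config.air_b0 + (config.trend_per_day - b1) * t_anchor
        noise = _ar1(rng.standard_normal(n + 1000), config.air_phi,
                     config.air_sd)[1000:]
        member = b0 + b1 * t + seasonal + noise
        name = f"m{i + 1:02d}"
        cells = []
        for c in range(n_cells):
            mid = member + (rng.normal(0.0, cell_sd, n) if cell_sd > 0 else 0.0)
            cmin, cmax = f"{name}_c{c}_min", f"{name}_c{c}_max"
            columns[cmin] = mid - half
            columns[cmax] = mid + half
            cells.append([cmin, cmax])
        layout["members"][name] = cells
    frame = pd.DataFrame(columns)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "ensemble.csv", index=False, date_format="%Y-%m-%d")
        with open(out_dir / "layout.yaml", "w") as fh:
            yaml.safe_dump(layout, fh)
    return frame, layout, trends
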