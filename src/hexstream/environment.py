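"""Hourly flow/temperature series, flow scenarios and the day/night calendar.

The simulator consumes an :class:`EnvironmentSeries`: hourly flow (m^3/s)
and water temperature (degC), daily turbidity (NTU, fixed zero in this
application), and a day/night phase calendar derived from latitude with a
twilight extension at dawn and dusk.

Water temperature for unmonitored periods is estimated from air
temperature with a seasonal-sinusoid-plus-residual-regression model
(:func:`fit_air_water_model`): both series are fit with a 365.25-day
sinusoid, water residuals are regressed on air residuals, predictions are
floored at 0 degC and offset by +0.5 degC so incubating eggs do not see
spurious sub-zero temperatures.

Flow scenario builders cap the base series at 30 m^3/s (the upper limit of
the hydraulic lookup) and impose minimum flows of 3, 6 or 9 m^3/s, or
scale a natural daily series to 10/20/33% (the SHYPE scenarios).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_math import ParameterError

__all__ = [
    "FittingError",
    "EnvironmentSeries",
    "AirWaterTempModel",
    "fit_air_water_model",
    "build_flow_scenario",
    "normalize_dst",
    "phase_calendar",
    "generate_synthetic_environment",
    "generate_synthetic_air_water",
    "FLOW_SCENARIOS",
]

PERIOD_DAYS = 365.25
DEFAULT_LATITUDE = 59.0  # degrees north

FLOW_SCENARIOS = ("Flow0", "Flow3", "Flow6", "Flow9",
                  "SHYPE1", "SHYPE2", "SHYPE3")
_SHYPE_FRACTIONS = {"SHYPE1": 0.10, "SHYPE2": 0.20, "SHYPE3": 0.33}
FLOW_CAP = 30.0  # m^3/s


class FittingError(ValueError):
    """Insufficient or degenerate data for a model fit."""


# ---------------------------------------------------------------------------
# day/night calendar
# ---------------------------------------------------------------------------

def _day_length_hours(day_of_year: np.ndarray, latitude: float) -> np.ndarray:
    """Astronomical day length from the standard solar-declination formula."""
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (day_of_year + 10) / PERIOD_DAYS)
    lat = np.deg2rad(latitude)
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return 2.0 * np.rad2deg(np.arccos(cos_omega)) / 15.0


def phase_calendar(index: pd.DatetimeIndex, latitude: float = DEFAULT_LATITUDE,
                   twilight_hours: float = 0.5):
    """Day/night phase and first-daylight-hour flags for an hourly index.

    Daylight is centred on 12:00 and extended by ``twilight_hours`` at each
    end; an hour counts as daylight when its midpoint falls inside the
    window.  Every calendar day has at least one daylight hour and exactly
    one hour flagged as its first daylight hour.
    """
    if not -66.0 < latitude < 66.0:
        raise ParameterError("polar latitudes are not supported")
    doy = index.dayofyear.to_numpy()
    daylen = _day_length_hours(doy, latitude) + 2.0 * twilight_hours
    half = daylen / 2.0
    hour_mid = index.hour.to_numpy() + 0.5
    phase_day = np.abs(hour_mid - 12.0) <= half

    # guarantee at least one daylight hour per day (short winter days)
    dates = index.normalize()
    df = pd.DataFrame({"day": phase_day}, index=index)
    any_day = df.groupby(dates)["day"].transform("any").to_numpy()
    noonish = index.hour.to_numpy() == 12
    phase_day = phase_day | (~any_day & noonish)

    first = np.zeros(len(index), dtype=bool)
    seen = {}
    for i, (d, p) in enumerate(zip(dates, phase_day)):
        if p and d not in seen:
            seen[d] = True
            first[i] = True
    return phase_day, first


# ---------------------------------------------------------------------------
# environment container
# ---------------------------------------------------------------------------

class EnvironmentSeries:
    """Hourly flow and temperature plus daily turbidity and phase calendar."""

    def __init__(self, flow: pd.Series, temperature: pd.Series,
                 turbidity: pd.Series | None = None,
                 latitude: float = DEFAULT_LATITUDE,
                 twilight_hours: float = 0.5):
        idx = flow.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise ParameterError("flow must be indexed by timestamps")
        if idx.has_duplicates:
            raise ParameterError("duplicate hourly timestamps")
        expected = pd.date_range(idx[0], idx[-1], freq="h")
        if len(idx) != len(expected) or not (idx == expected).all():
            raise ParameterError("hourly series has gaps or irregular spacing")
        if not temperature.index.equals(idx):
            raise ParameterError("flow and temperature must share their index")
        if (flow < 0).any():
            raise ParameterError("flow must be non-negative")

        self.index = idx
        self.flow = flow.to_numpy(float)
        self.temperature = temperature.to_numpy(float)
        if turbidity is None:
            days = pd.date_range(idx[0].normalize(), idx[-1].normalize(), freq="D")
            turbidity = pd.Series(0.0, index=days)
        if (turbidity < 0).any():
            raise ParameterError("turbidity must be non-negative")
        self.turbidity = turbidity
        self.latitude = latitude
        self.twilight_hours = twilight_hours
        self.phase_day, self.first_daylight = phase_calendar(
            idx, latitude, twilight_hours)

        dates = idx.normalize()
        self.daily_mean_temp = pd.Series(self.temperature, index=idx) \
            .groupby(dates).mean()
        self.daily_max_flow = pd.Series(self.flow, index=idx) \
            .groupby(dates).max()

    def __len__(self) -> int:
        return len(self.index)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "flow_m3s": self.flow, "temp_C": self.temperature,
            "phase_day": self.phase_day,
            "first_daylight": self.first_daylight}, index=self.index)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"flow_m3s": self.flow, "temp_C": self.temperature},
                          index=self.index)
        df.index.name = "timestamp"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "EnvironmentSeries":
        df = pd.read_csv(path, index_col="timestamp", parse_dates=True)
        return cls(df["flow_m3s"], df["temp_C"], **kwargs)


# ---------------------------------------------------------------------------
# air -> water temperature model
# ---------------------------------------------------------------------------

def _fit_sinusoid(values: pd.Series):
    """Least-squares 365.25-day sinusoid; returns (mean, amp, phase_day)."""
    t = values.index.dayofyear.to_numpy(float)
    omega = 2 * np.pi / PERIOD_DAYS
    X = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    beta, *_ = np.linalg.lstsq(X, values.to_numpy(float), rcond=None)
    mean, bc, bs = beta
    amp = math.hypot(bc, bs)
    phase_day = math.atan2(bs, bc) / omega % PERIOD_DAYS
    return float(mean), float(amp), float(phase_day)


@dataclass(frozen=True)
class AirWaterTempModel:
    """Seasonal sinusoids plus residual regression; floored at 0, +0.5 degC."""

    air_mean: float
    air_amplitude: float
    air_phase_day: float
    water_mean: float
    water_amplitude: float
    water_phase_day: float
    slope: float
    intercept: float
    floor: float = 0.0
    offset: float = 0.5

    def _sinusoid(self, day_of_year, mean, amp, phase_day):
        omega = 2 * np.pi / PERIOD_DAYS
        return mean + amp * np.cos(omega * (np.asarray(day_of_year, float)
                                            - phase_day))

    def predict(self, air_daily: pd.Series) -> pd.Series:
        """Predicted daily water temperature (degC, >= 0.5) from daily air."""
        doy = air_daily.index.dayofyear.to_numpy(float)
        air_resid = air_daily.to_numpy(float) - self._sinusoid(
            doy, self.air_mean, self.air_amplitude, self.air_phase_day)
        water = self._sinusoid(
            doy, self.water_mean, self.water_amplitude, self.water_phase_day) \
            + self.slope * air_resid + self.intercept
        water = np.maximum(water, self.floor) + self.offset
        return pd.Series(water, index=air_daily.index)


def fit_air_water_model(air_daily: pd.Series, water_daily: pd.Series
                        ) -> AirWaterTempModel:
    """Fit the simplified air-to-water temperature model.

    Requires at least a full year of daily air data and 30 days of water
    data overlapping the air record.
    """
    air_daily = air_daily.dropna()
    water_daily = water_daily.dropna()
    if (air_daily.index.max() - air_daily.index.min()).days < 365:
        raise FittingError("need at least one year of daily air temperatures")
    overlap = water_daily.index.intersection(air_daily.index)
    if len(overlap) < 30:
        raise FittingError("need >= 30 days of water data overlapping air data")

    a_mean, a_amp, a_phase = _fit_sinusoid(air_daily)
    w_mean, w_amp, w_phase = _fit_sinusoid(water_daily)

    model0 = AirWaterTempModel(a_mean, a_amp, a_phase, w_mean, w_amp, w_phase,
                               0.0, 0.0)
    doy = overlap.dayofyear.to_numpy(float)
    air_resid = air_daily.loc[overlap].to_numpy(float) - model0._sinusoid(
        doy, a_mean, a_amp, a_phase)
    water_resid = water_daily.loc[overlap].to_numpy(float) - model0._sinusoid(
        doy, w_mean, w_amp, w_phase)
    var = float(np.var(air_resid))
    if var < 1e-12:
        # constant air residuals: regression degenerates to intercept only
        slope, intercept = 0.0, float(np.mean(water_resid))
    else:
        slope, intercept = np.polyfit(air_resid, water_resid, 1)
    return AirWaterTempModel(a_mean, a_amp, a_phase, w_mean, w_amp, w_phase,
                             float(slope), float(intercept))


# ---------------------------------------------------------------------------
# flow scenarios
# ---------------------------------------------------------------------------

def build_flow_scenario(base_hourly: pd.Series, scenario: str,
                        natural_daily: pd.Series | None = None,
                        cap_shype: bool = False) -> pd.Series:
    """Build an hourly flow series for a named scenario.

    ``Flow0`` caps the base series at 30 m^3/s; ``Flow3/6/9`` additionally
    impose that minimum flow.  ``SHYPE1/2/3`` scale a *natural* daily
    series to 10/20/33% and expand it to hourly (uncapped unless
    ``cap_shype``).
    """
    if scenario not in FLOW_SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; valid: {', '.join(FLOW_SCENARIOS)}")
    if scenario.startswith("Flow"):
        q = np.minimum(base_hourly.to_numpy(float), FLOW_CAP)
        floor = float(scenario[4:])
        if floor > 0:
            q = np.maximum(q, floor)
        return pd.Series(q, index=base_hourly.index)
    if natural_daily is None:
        raise ParameterError(f"{scenario} needs a natural daily flow series")
    frac = _SHYPE_FRACTIONS[scenario]
    hourly_index = pd.date_range(
        natural_daily.index[0],
        natural_daily.index[-1] + pd.Timedelta(hours=23), freq="h")
    q = (frac * natural_daily).reindex(hourly_index.normalize()).to_numpy(float)
    if cap_shype:
        q = np.minimum(q, FLOW_CAP)
    return pd.Series(q, index=hourly_index)


def normalize_dst(series: pd.Series) -> pd.Series:
    """Repair daylight-saving artefacts in an hourly series.

    Removes duplicated hours (first record kept) and fills single missing
    hours with the preceding value; multi-hour gaps raise an error naming
    the first missing timestamp.
    """
    s = series[~series.index.duplicated(keep="first")].sort_index()
    full = pd.date_range(s.index[0], s.index[-1], freq="h")
    missing = full.difference(s.index)
    if len(missing):
        gaps = missing.to_series().diff().dt.total_seconds().fillna(7200.0)
        run = (gaps <= 3600.0)
        if run.any():
            bad = missing[run.to_numpy()][0]
            raise ParameterError(f"multi-hour gap at {bad}")
    return s.reindex(full).ffill()


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------

def _water_sinusoid(doy: np.ndarray, mean=10.25, amp=9.75, peak_doy=200.0):
    return mean + amp * np.cos(2 * np.pi * (doy - peak_doy) / PERIOD_DAYS)


def generate_synthetic_environment(
    years: int,
    seed: int = 0,
    *,
    start: str = "2008-09-20",
    base_flow: float = 3.0,
    spike_prob: float = 0.01,
    temp_mean: float = 10.25,
    temp_amplitude: float = 9.75,
    temp_peak_doy: float = 200.0,
    temp_noise_sd: float = 0.4,
    latitude: float = DEFAULT_LATITUDE,
) -> EnvironmentSeries:
    """Seeded synthetic regulated-reach environment.

    Flow: near-constant base flow with AR(1) excursions and occasional
    multi-day spikes (the regulated-release pattern).  Water temperature: a
    seasonal sinusoid between about 0.5 and 20 degC with autocorrelated
    daily noise, the daily mean repeated for all 24 hours of each day.
    Turbidity is zero throughout.
    """
    if years < 1:
        raise ParameterError("years must be >= 1")
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start)
    index = pd.date_range(t0, t0 + pd.DateOffset(years=years), freq="h",
                          inclusive="left")
    days = pd.date_range(index[0].normalize(), index[-1].normalize(), freq="D")
    nd = len(days)

    # daily flow: AR(1) around base flow plus rare decaying spikes
    eps = rng.normal(0.0, 0.15, size=nd)
    x = np.empty(nd)
    x[0] = 0.0
    for i in range(1, nd):
        x[i] = 0.9 * x[i - 1] + eps[i]
    daily_flow = base_flow * np.exp(x - x.var() / 2)
    spikes = rng.random(nd) < spike_prob
    magnitude = rng.uniform(10.0, 40.0, size=nd)
    for i in np.flatnonzero(spikes):
        for k in range(3):
            if i + k < nd:
                daily_flow[i + k] += magnitude[i] * 0.5 ** k
    daily_flow = np.maximum(daily_flow, 0.5)

    # daily temperature: sinusoid + AR(1) noise, floored at 0.5 degC
    doy = days.dayofyear.to_numpy(float)
    noise = np.empty(nd)
    noise[0] = 0.0
    eta = rng.normal(0.0, temp_noise_sd, size=nd)
    for i in range(1, nd):
        noise[i] = 0.7 * noise[i - 1] + eta[i]
    daily_temp = np.maximum(
        _water_sinusoid(doy, temp_mean, temp_amplitude, temp_peak_doy) + noise,
        0.5)

    day_pos = ((index.normalize() - days[0]) // pd.Timedelta(days=1)).to_numpy()
    flow = pd.Series(daily_flow[day_pos], index=index)
    temp = pd.Series(daily_temp[day_pos], index=index)
    return EnvironmentSeries(flow, temp, latitude=latitude)


def generate_synthetic_air_water(
    years: int = 3,
    seed: int = 0,
    *,
    air_mean: float = 6.0,
    air_amplitude: float = 11.0,
    air_peak_doy: float = 200.0,
    water_mean: float = 9.0,
    water_amplitude: float = 8.0,
    water_peak_doy: float = 215.0,
    slope: float = 0.35,
    air_resid_sd: float = 2.0,
    noise_sd: float = 0.3,
    start: str = "2010-01-01",
):
    """Paired daily air/water series from a known sinusoid+residual model.

    Used to exercise parameter recovery in :func:`fit_air_water_model`:
    water = water sinusoid + ``slope`` * (air residual) + noise.
    """
    rng = np.random.default_rng(seed)
    days = pd.date_range(start, periods=int(years * 365.25), freq="D")
    doy = days.dayofyear.to_numpy(float)
    air_resid = rng.normal(0.0, air_resid_sd, size=len(days))
    air = _water_sinusoid(doy, air_mean, air_amplitude, air_peak_doy) + air_resid
    water = _water_sinusoid(doy, water_mean, water_amplitude, water_peak_doy) \
        + slope * air_resid + rng.normal(0.0, noise_sd, size=len(days))
    return pd.Series(air, index=days), pd.Series(water, index=days)
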