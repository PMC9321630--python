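"""Synthetic sub-daily meteorological forcing and the SPI drought index.

The generator emulates 3-hourly Southern Hemisphere station weather:
shortwave radiation from solar geometry (clear-sky transmissivity,
attenuated on rain days), air temperature with seasonal and diurnal
cycles plus AR(1) day-to-day noise, vapour pressure consistent with a
bounded relative humidity, and rainfall as a Bernoulli daily-occurrence /
gamma-depth process tuned to a target mean annual precipitation. A
"drought block" option suppresses rain-day frequency over a chosen span
to create control-versus-drought experiment pairs.

The Standardised Precipitation Index (SPI) follows the McKee
construction: rolling precipitation sums are fitted with a gamma
distribution over a baseline (zero totals handled with a mixed
discrete-continuous CDF) and mapped through standard normal quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import P_ATM_DEFAULT
from .photosyn import saturation_vapour_pressure

__all__ = ["ClimateSpec", "generate_forcing", "perturb_forcing", "spi"]

FORCING_COLUMNS = ("SW_down", "T_air", "e_air", "precip", "wind", "P_atm", "CO2")

SOLAR_CONSTANT = 1361.0  # W m-2
CLEAR_SKY_TRANSMISSIVITY = 0.72
RAINY_SKY_TRANSMISSIVITY = 0.35


@dataclass(frozen=True)
class ClimateSpec:
    """Statistical climate targets for the generator.

    map_mm_yr: mean annual precipitation target; rain_day_freq: Bernoulli
    daily occurrence probability; temperatures degC; latitude degrees
    (negative = Southern Hemisphere); co2 umol mol-1.
    """

    map_mm_yr: float = 700.0
    rain_day_freq: float = 0.18
    t_mean: float = 17.0
    t_seasonal_amplitude: float = 7.0
    t_diurnal_amplitude: float = 6.0
    latitude: float = -33.0
    co2: float = 400.0
    drought_start: pd.Timestamp | None = None
    drought_end: pd.Timestamp | None = None
    drought_rain_factor: float = 0.35

    def __post_init__(self) -> None:
        if self.map_mm_yr <= 0 or not 0 < self.rain_day_freq <= 1:
            raise ValueError("require map_mm_yr > 0 and rain_day_freq in (0, 1]")


def _solar_elevation_sin(doy: np.ndarray, hour: np.ndarray, latitude: float) -> np.ndarray:
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    lat = np.deg2rad(latitude)
    hour_angle = np.deg2rad(15.0 * (hour - 12.0))
    return np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)


def generate_forcing(
    spec: ClimateSpec,
    years: int,
    timestep: float = 10800.0,
    seed: int = 0,
    start: str = "2017-01-01",
) -> pd.DataFrame:
    """Generate a regular forcing time series (DataFrame, DatetimeIndex).

    Columns: SW_down (W m-2), T_air (degC), e_air (kPa), precip (mm per
    step), wind (m s-1), P_atm (kPa), CO2 (umol mol-1). Reproducible from
    ``seed``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    steps_per_day = int(round(86400.0 / timestep))
    if abs(steps_per_day * timestep - 86400.0) > 1e-6:
        raise ValueError("timestep must divide the day")

    start_ts = pd.Timestamp(start)
    end_ts = start_ts + pd.DateOffset(years=years)
    index = pd.date_range(start_ts, end_ts, freq=f"{int(timestep)}s", inclusive="left")
    n = len(index)
    days = pd.date_range(start_ts, end_ts, freq="D", inclusive="left")
    n_days = len(days)
    doy = index.dayofyear.to_numpy().astype(float)
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0

    # --- rainfall: daily occurrence x gamma depth, spread over the day ---
    p_rain = np.full(n_days, spec.rain_day_freq)
    if spec.drought_start is not None and spec.drought_end is not None:
        in_block = (days >= spec.drought_start) & (days <= spec.drought_end)
        p_rain[in_block] *= spec.drought_rain_factor
    rain_day = rng.random(n_days) < p_rain
    mean_depth = spec.map_mm_yr / (365.25 * spec.rain_day_freq)
    shape = 0.8
    depths = rng.gamma(shape, mean_depth / shape, size=n_days) * rain_day
    day_index = ((index.normalize() - start_ts.normalize()).days).to_numpy()
    precip = depths[day_index] / steps_per_day

    # --- temperature: seasonal + diurnal + AR(1) daily anomaly ----------
    # southern hemisphere: warmest near mid-January (doy ~ 15)
    season_phase = 2 * np.pi * (doy - 15.0) / 365.0
    sign = 1.0 if spec.latitude < 0 else -1.0
    seasonal = sign * spec.t_seasonal_amplitude * np.cos(season_phase)
    anom_daily = np.empty(n_days)
    rho, sd = 0.7, 2.0
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n_days)
    anom_daily[0] = rng.normal(0.0, sd)
    for i in range(1, n_days):
        anom_daily[i] = rho * anom_daily[i - 1] + eps[i]
    diurnal = spec.t_diurnal_amplitude * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    t_air = spec.t_mean + seasonal + diurnal + anom_daily[day_index]

    # --- shortwave from solar geometry ----------------------------------
    sin_elev = np.maximum(_solar_elevation_sin(doy, hour, spec.latitude), 0.0)
    tau = np.where(rain_day[day_index], RAINY_SKY_TRANSMISSIVITY, CLEAR_SKY_TRANSMISSIVITY)
    sw = SOLAR_CONSTANT * tau * sin_elev

    # --- humidity: bounded daily relative humidity -----------------------
    rh_daily = np.clip(
        rng.normal(0.55, 0.12, size=n_days) + 0.25 * rain_day, 0.2, 1.0
    )
    e_air = rh_daily[day_index] * saturation_vapour_pressure(t_air)

    wind = np.clip(rng.normal(2.5, 0.8, size=n_days), 0.5, None)[day_index]

    return pd.DataFrame(
        {
            "SW_down": sw,
            "T_air": t_air,
            "e_air": e_air,
            "precip": precip,
            "wind": wind,
            "P_atm": P_ATM_DEFAULT,
            "CO2": spec.co2,
        },
        index=index,
    )


def perturb_forcing(
    forcing: pd.DataFrame, precip_scale: float = 1.0, co2_scale: float = 1.0
) -> pd.DataFrame:
    """Uniformly scale precipitation and CO2; all other fields unchanged."""
    if precip_scale <= 0 or co2_scale <= 0:
        raise ValueError("scales must be positive")
    out = forcing.copy()
    out["precip"] = out["precip"] * precip_scale
    out["CO2"] = out["CO2"] * co2_scale
    return out


def _fit_gamma(values: np.ndarray) -> tuple[float, float]:
    """MLE gamma fit (floc=0) with the Thom closed-form approximation fallback."""
    try:
        shape, _, scale = stats.gamma.fit(values, floc=0.0)
        if np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0:
            return shape, scale
    except Exception:
        pass
    # Thom (1958) approximation
    a_stat = np.log(values.mean()) - np.mean(np.log(values))
    shape = (1.0 + np.sqrt(1.0 + 4.0 * a_stat / 3.0)) / (4.0 * a_stat)
    return shape, values.mean() / shape


def spi(
    monthly_precip: pd.Series,
    window: int = 6,
    baseline: slice | None = None,
) -> pd.Series:
    """Standardised Precipitation Index of a monthly precipitation series.

    ``window``-month rolling sums are fitted with a gamma distribution
    over the baseline period (default: the whole series); zero sums are
    absorbed into a mixed CDF H(x) = q + (1 - q) G(x) with q the zero
    frequency. Each sum is mapped through H then the standard normal
    quantile. Requires >= 30 baseline window sums.
    """
    sums = monthly_precip.rolling(window).sum().dropna()
    base = sums if baseline is None else sums.loc[baseline]
    base_vals = base.to_numpy(dtype=float)
    if base_vals.size < 30:
        raise ValueError(
            f"need >= 30 baseline window sums to fit the gamma, got {base_vals.size}"
        )
    positive = base_vals[base_vals > 0]
    if positive.size < 2:
        raise ValueError("baseline is (almost) entirely zero precipitation")
    q = float((base_vals == 0).mean())
    shape, scale = _fit_gamma(positive)

    x = sums.to_numpy(dtype=float)
    g = stats.gamma.cdf(x, shape, scale=scale)
    h = np.where(x > 0, q + (1.0 - q) * g, q / 2.0 if q > 0 else 0.0)
    h = np.clip(h, 1e-9, 1 - 1e-9)
    return pd.Series(stats.norm.ppf(h), index=sums.index, name="SPI")
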