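"""Seeded synthetic inputs: daily weather, soil profiles, cell grids,
monthly normals and per-GCM monthly change signals.

Everything here is deterministic for a fixed seed so the downstream
pipeline is fully testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .water_balance import SoilLayer, SoilProfile

__all__ = [
    "WeatherGenParams",
    "GcmDeltaParams",
    "MonthlyNormals",
    "gen_daily_weather",
    "gen_soil_profile",
    "gen_cell_grid",
    "gen_gcm_delta_params",
    "apply_monthly_normals",
    "global_grid_shape",
    "global_grid_size",
    "grid_cell_center",
    "GRID_RESOLUTION_DEG",
    "SAND_EXCLUSION_LIMIT",
]

GRID_RESOLUTION_DEG = 0.3125
SAND_EXCLUSION_LIMIT = 0.90

_NORTH_COLD_MONTHS = (12, 1, 2)
_SOUTH_COLD_MONTHS = (6, 7, 8)


# ---------------------------------------------------------------------------
# weather generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeatherGenParams:
    """Parameters of the synthetic daily weather generator.

    ``precip_seasonality`` is the fraction of annual precipitation that
    falls in the three climatologically coldest months (DJF north of the
    equator, JJA south of it).  The generated series is rescaled so that
    realized MAT and MAP match their targets by construction.
    """

    mat_target: float  # deg C
    map_target: float  # mm / yr
    temp_seasonal_amplitude: float = 12.0  # deg C
    precip_seasonality: float = 0.25
    wet_day_prob: float = 0.25
    interannual_cv: float = 0.15
    years: int = 31
    seed: int = 0
    latitude: float = 40.0
    diurnal_range: float = 10.0  # deg C, tmax - tmin
    start_year: int = 2000

    def __post_init__(self) -> None:
        if self.map_target <= 0:
            raise ValueError("map_target must be > 0")
        if self.years < 2:
            raise ValueError("years must be >= 2")
        if not 0 <= self.precip_seasonality <= 1:
            raise ValueError("precip_seasonality must be in [0, 1]")
        if not 0 < self.wet_day_prob <= 1:
            raise ValueError("wet_day_prob must be in (0, 1]")
        if self.interannual_cv < 0:
            raise ValueError("interannual_cv must be >= 0")
        if self.temp_seasonal_amplitude < 0:
            raise ValueError("temp_seasonal_amplitude must be >= 0")


def _cold_months(latitude: float) -> tuple[int, ...]:
    return _NORTH_COLD_MONTHS if latitude >= 0 else _SOUTH_COLD_MONTHS


def _monthly_precip_weights(params: WeatherGenParams) -> np.ndarray:
    """Per-month share of annual precipitation implied by the seasonality."""
    cold = _cold_months(params.latitude)
    weights = np.empty(12)
    for m in range(1, 13):
        if m in cold:
            weights[m - 1] = params.precip_seasonality / 3.0
        else:
            weights[m - 1] = (1.0 - params.precip_seasonality) / 9.0
    return weights


def gen_daily_weather(params: WeatherGenParams) -> pd.DataFrame:
    """Generate a daily weather series (date, tmax, tmin, precip).

    Temperature: sinusoidal annual cycle (365.25-day phase, coldest in
    mid-January north of the equator, mid-July south of it) plus AR(1)
    daily noise, recentered so the realized multi-year mean equals
    ``mat_target`` exactly.  Precipitation: two-state occurrence with
    monthly-varying wet-day probability and exponential amounts,
    modulated by a lognormal interannual factor, then rescaled so the
    realized mean annual total equals ``map_target`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(f"{params.start_year}-01-01",
                          f"{params.start_year + params.years - 1}-12-31",
                          freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    year = dates.year.to_numpy()

    # annual temperature cycle; phase set so day 15 is the coldest (north)
    phase = 2.0 * np.pi * (doy - 15) / 365.25
    sign = -1.0 if params.latitude >= 0 else 1.0
    tmean = params.mat_target + sign * params.temp_seasonal_amplitude * np.cos(phase)

    # AR(1) noise
    rho, sigma = 0.7, 2.0
    eps = rng.normal(0.0, sigma * math.sqrt(1 - rho * rho), size=n)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, sigma)
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + eps[i]
    tmean = tmean + noise
    tmean += params.mat_target - tmean.mean()  # exact MAT by construction

    tmax = tmean + params.diurnal_range / 2.0
    tmin = tmean - params.diurnal_range / 2.0

    # precipitation
    weights = _monthly_precip_weights(params)
    mean_w = weights[weights > 0].mean() if np.any(weights > 0) else 0.0
    precip = np.zeros(n)
    if mean_w > 0:
        p_month = np.clip(params.wet_day_prob * weights / mean_w, 0.0, 1.0)
        days_per_month = np.array([pd.Timestamp(2001, m, 1).days_in_month
                                   for m in range(1, 13)], dtype=float)
        wet = rng.random(n) < p_month[month - 1]
        # mean wet-day amount so that expected monthly totals match weights
        mu = np.zeros(12)
        for m in range(12):
            if p_month[m] > 0:
                mu[m] = (params.map_target * weights[m]
                         / (p_month[m] * days_per_month[m]))
        amounts = rng.exponential(1.0, size=n) * mu[month - 1]
        precip = np.where(wet, amounts, 0.0)
        if params.interannual_cv > 0:
            sigma_ln = math.sqrt(math.log(1 + params.interannual_cv ** 2))
            factors = rng.lognormal(-0.5 * sigma_ln ** 2, sigma_ln,
                                    size=params.years)
            year_index = year - params.start_year
            precip = precip * factors[year_index]
        total = precip.sum()
        if total > 0:
            precip *= params.map_target * params.years / total  # exact MAP

    return pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin,
                         "precip": precip})


# ---------------------------------------------------------------------------
# soil profiles
# ---------------------------------------------------------------------------


def gen_soil_profile(sand: float, clay: float, total_depth: float) -> SoilProfile:
    """Build a layered profile: 0-10 and 10-20 cm surface layers, then
    20 cm increments down to ``total_depth`` (last layer truncated if the
    depth is not a multiple of 20).
    """
    if not (0 <= sand <= 1 and 0 <= clay <= 1 and sand + clay <= 1):
        raise ValueError("sand and clay must be fractions with sand + clay <= 1")
    if total_depth < 20:
        raise ValueError("total_depth must be >= 20 cm")
    bounds = [0.0, 10.0, 20.0]
    d = 20.0
    while d < total_depth:
        d = min(d + 20.0, float(total_depth))
        bounds.append(d)
    layers = tuple(SoilLayer.from_texture(t, b, sand, clay)
                   for t, b in zip(bounds, bounds[1:]))
    return SoilProfile(layers=layers)


# ---------------------------------------------------------------------------
# global raster geometry
# ---------------------------------------------------------------------------


def global_grid_shape(resolution: float = GRID_RESOLUTION_DEG) -> tuple[int, int]:
    """(n_lon, n_lat) of the global raster at the given resolution."""
    n_lon = round(360.0 / resolution)
    n_lat = round(180.0 / resolution)
    return n_lon, n_lat


def global_grid_size(resolution: float = GRID_RESOLUTION_DEG) -> int:
    """Total number of cells of the global raster."""
    n_lon, n_lat = global_grid_shape(resolution)
    return n_lon * n_lat


def grid_cell_center(i_lat: int, j_lon: int,
                     resolution: float = GRID_RESOLUTION_DEG) -> tuple[float, float]:
    """(lat, lon) of the center of grid cell (i_lat, j_lon); origin at
    90 deg S / 180 deg W, so the first center sits at half a cell width
    from each edge."""
    lat = -90.0 + (i_lat + 0.5) * resolution
    lon = -180.0 + (j_lon + 0.5) * resolution
    return lat, lon


# ---------------------------------------------------------------------------
# cell grids
# ---------------------------------------------------------------------------

_ARCHETYPES = ("temperate_dryland", "subtropical", "boreal", "too_wet", "too_sandy")
_REGIONS = ("South America", "Eastern Asia", "Western and Central Asia",
            "Western Mediterranean", "North America")


def _archetype_params(arch: str, rng: np.random.Generator) -> dict:
    u = rng.random
    if arch == "temperate_dryland":
        return dict(mat=6 + 4 * u(), amplitude=14 + 4 * u(), map_mm=250 + 100 * u(),
                    seasonality=0.30 + 0.15 * u(), sand=0.35 + 0.15 * u(),
                    clay=0.15 + 0.10 * u(), lat_band=(35, 48))
    if arch == "subtropical":
        return dict(mat=16 + 4 * u(), amplitude=6 + 3 * u(), map_mm=250 + 100 * u(),
                    seasonality=0.25, sand=0.4, clay=0.2, lat_band=(25, 33))
    if arch == "boreal":
        return dict(mat=-1 + 2 * u(), amplitude=15 + 3 * u(), map_mm=300,
                    seasonality=0.25, sand=0.4, clay=0.2, lat_band=(55, 65))
    if arch == "too_wet":
        return dict(mat=6 + 4 * u(), amplitude=14 + 4 * u(), map_mm=1000 + 300 * u(),
                    seasonality=0.30, sand=0.4, clay=0.2, lat_band=(35, 48))
    if arch == "too_sandy":
        return dict(mat=6 + 4 * u(), amplitude=14 + 4 * u(), map_mm=250 + 100 * u(),
                    seasonality=0.30, sand=0.93 + 0.04 * u(), clay=0.03,
                    lat_band=(35, 48))
    raise ValueError(f"unknown archetype {arch!r}")


def gen_cell_grid(n_cells: int, seed: int = 0, stratified: bool = True) -> pd.DataFrame:
    """Generate a table of synthetic cells spanning the classification space.

    With ``stratified`` the archetypes (temperate dryland, subtropical,
    boreal, too-wet, too-sandy) are cycled so every classifier outcome is
    represented as soon as n_cells >= 5.  Cell centers snap to the
    0.3125-degree global raster.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cells):
        arch = _ARCHETYPES[c % len(_ARCHETYPES)] if stratified \
            else str(rng.choice(_ARCHETYPES))
        p = _archetype_params(arch, rng)
        lo, hi = p["lat_band"]
        i_lat = int((rng.uniform(lo, hi) + 90.0) / GRID_RESOLUTION_DEG)
        j_lon = int(rng.integers(0, global_grid_shape()[0]))
        lat, lon = grid_cell_center(i_lat, j_lon)
        rows.append(dict(
            cell_id=c, lat=lat, lon=lon,
            region=_REGIONS[c % len(_REGIONS)], archetype=arch,
            mat_target=p["mat"], map_target=p["map_mm"],
            temp_seasonal_amplitude=p["amplitude"],
            precip_seasonality=p["seasonality"],
            wet_day_prob=0.25, interannual_cv=0.15,
            sand=p["sand"], clay=p["clay"], soil_depth_cm=100.0,
            rh_pct=50.0 + 20.0 * rng.random(),
            wind_ms=2.0 + 2.0 * rng.random(),
            cloud_frac=0.3 + 0.3 * rng.random(),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# monthly normals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonthlyNormals:
    """Monthly climate normals of a daily series."""

    monthly_temp: np.ndarray  # 12 mean temperatures, deg C
    monthly_precip: np.ndarray  # 12 mean monthly totals, mm
    mat: float
    map: float


def apply_monthly_normals(weather: pd.DataFrame) -> MonthlyNormals:
    """Monthly mean temperatures and mean monthly precipitation totals.

    Monthly temperature normals are the across-year means of per-year
    monthly mean temperatures; precipitation normals are across-year
    means of per-year monthly sums.  MAT averages the 12 temperature
    normals, MAP sums the 12 precipitation normals.  Requires complete
    calendar years.
    """
    dates = pd.DatetimeIndex(weather["date"])
    first, last = dates[0], dates[-1]
    if not (first.month == 1 and first.day == 1 and last.month == 12 and last.day == 31):
        raise ValueError("weather series must cover complete calendar years")
    tmean = 0.5 * (weather["tmax"].to_numpy(float) + weather["tmin"].to_numpy(float))
    df = pd.DataFrame({"year": dates.year, "month": dates.month,
                       "tmean": tmean, "precip": weather["precip"].to_numpy(float)})
    per_ym = df.groupby(["year", "month"]).agg(
        tmean=("tmean", "mean"), precip=("precip", "sum"))
    normals = per_ym.groupby(level="month").mean()
    t12 = normals["tmean"].to_numpy()
    p12 = normals["precip"].to_numpy()
    return MonthlyNormals(monthly_temp=t12, monthly_precip=p12,
                          mat=float(t12.mean()), map=float(p12.sum()))


# ---------------------------------------------------------------------------
# GCM delta parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GcmDeltaParams:
    """Monthly change signal of one synthetic GCM."""

    temp_delta_by_month: tuple[float, ...]  # 12 additive deltas, deg C
    precip_ratio_by_month: tuple[float, ...]  # 12 multiplicative ratios
    gcm_label: str = "GCM"

    def __post_init__(self) -> None:
        if len(self.temp_delta_by_month) != 12 or len(self.precip_ratio_by_month) != 12:
            raise ValueError("need 12 monthly entries each")
        if any(r <= 0 for r in self.precip_ratio_by_month):
            raise ValueError("precip ratios must be strictly positive")


def gen_gcm_delta_params(n_gcms: int, seed: int = 0,
                         warming_range: tuple[float, float] = (3.0, 7.0),
                         precip_ratio_range: tuple[float, float] = (0.8, 1.2),
                         ) -> list[GcmDeltaParams]:
    """Random per-GCM monthly deltas: warming within ``warming_range`` and
    precipitation ratios within ``precip_ratio_range``."""
    if n_gcms < 1:
        raise ValueError("n_gcms must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for g in range(n_gcms):
        base_warm = rng.uniform(*warming_range)
        temp = tuple(float(base_warm + rng.normal(0, 0.5)) for _ in range(12))
        ratios = tuple(float(max(0.05, rng.uniform(*precip_ratio_range)))
                       for _ in range(12))
        out.append(GcmDeltaParams(temp, ratios, gcm_label=f"GCM{g:02d}"))
    return out
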