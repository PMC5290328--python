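"""Daily multi-layer ecosystem water balance for a single cell.

Processes: potential evapotranspiration (Penman-family combination
equation with an explicit day-length dependence), rain/snow partitioning
and degree-day melt, canopy+litter interception, cascading-bucket
infiltration/percolation, bare-soil evaporation, per-layer per-group
transpiration limited by soil-water-potential stress functions,
hydraulic redistribution, and deep drainage.

Water bookkeeping closes to machine precision every day:

    precip - d(swe) - d(storage) =
        interception + bare_soil_evap + transpiration + deep_drainage
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SoilState",
    "WaterBalanceParams",
    "SimulationResult",
    "swp_from_theta",
    "theta_from_swp",
    "day_length_hours",
    "pet_daily",
    "partition_precip_snow",
    "melt_snow",
    "intercept",
    "infiltrate_and_percolate",
    "bare_soil_evap",
    "transpire",
    "hydraulic_redistribute",
    "simulate",
]

# unit conversions
_CM_H2O_TO_MPA = 9.80665e-5
_LATENT_HEAT = 2.45  # MJ kg-1 (== MJ per mm of evaporated water)
_STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1
_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


# ---------------------------------------------------------------------------
# soil description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoilLayer:
    """One soil layer: geometry, texture and retention parameters.

    ``psi_sat`` is the air-entry potential in MPa (negative); ``b`` the
    Campbell retention-curve exponent.  ``field_capacity`` and
    ``wilting_point`` are volumetric water contents at -0.033 and
    -1.5 MPa respectively.
    """

    depth_top: float  # cm
    depth_bottom: float  # cm
    sand: float
    clay: float
    theta_sat: float
    psi_sat: float  # MPa, < 0
    b: float
    field_capacity: float
    wilting_point: float

    def __post_init__(self) -> None:
        if self.depth_bottom <= self.depth_top:
            raise ValueError("layer must have positive thickness")
        if not (0 < self.wilting_point < self.field_capacity < self.theta_sat):
            raise ValueError("require 0 < wilting_point < field_capacity < theta_sat")
        if self.psi_sat >= 0:
            raise ValueError("psi_sat must be negative (MPa)")

    @property
    def thickness_cm(self) -> float:
        return self.depth_bottom - self.depth_top

    @property
    def thickness_mm(self) -> float:
        return self.thickness_cm * 10.0

    @classmethod
    def from_texture(cls, depth_top: float, depth_bottom: float,
                     sand: float, clay: float) -> "SoilLayer":
        """Derive retention parameters from texture (Cosby-type regressions)."""
        if not (0 <= sand <= 1 and 0 <= clay <= 1 and sand + clay <= 1):
            raise ValueError("sand, clay must be fractions with sand + clay <= 1")
        theta_sat = 0.489 - 0.126 * sand
        psi_sat = -(10.0 ** (1.88 - 1.31 * sand)) * _CM_H2O_TO_MPA
        b = 2.91 + 15.9 * clay
        fc = theta_sat * (-0.033 / psi_sat) ** (-1.0 / b)
        wp = theta_sat * (-1.5 / psi_sat) ** (-1.0 / b)
        return cls(depth_top, depth_bottom, sand, clay, theta_sat, psi_sat, b, fc, wp)


@dataclass(frozen=True)
class SoilProfile:
    """Ordered stack of :class:`SoilLayer` from the surface downward."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if not math.isclose(upper.depth_bottom, lower.depth_top):
                raise ValueError("layers must be contiguous")

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def total_depth_cm(self) -> float:
        return self.layers[-1].depth_bottom

    @property
    def sand_max(self) -> float:
        return max(l.sand for l in self.layers)

    @property
    def thickness_mm(self) -> np.ndarray:
        return np.array([l.thickness_mm for l in self.layers])

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(l, attr) for l in self.layers])


@dataclass
class SoilState:
    """Evolving per-layer volumetric water content plus snowpack."""

    theta: np.ndarray  # volumetric fraction per layer
    swe: float = 0.0  # snow water equivalent, mm

    def copy(self) -> "SoilState":
        return SoilState(self.theta.copy(), self.swe)

    def storage_mm(self, profile: SoilProfile) -> float:
        return float(np.sum(self.theta * profile.thickness_mm))


# ---------------------------------------------------------------------------
# retention curve
# ---------------------------------------------------------------------------


def swp_from_theta(theta, layer: SoilLayer):
    """Soil water potential (MPa) from volumetric water content.

    Campbell power-law curve psi = psi_sat * (theta/theta_sat)**(-b).
    Accepts scalars or arrays; theta above saturation is treated as
    saturated.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be > 0")
    rel = np.minimum(theta / layer.theta_sat, 1.0)
    psi = layer.psi_sat * rel ** (-layer.b)
    return float(psi) if psi.ndim == 0 else psi


def theta_from_swp(psi, layer: SoilLayer):
    """Inverse retention curve; psi in MPa (<= psi_sat)."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi >= 0):
        raise ValueError("psi must be negative (MPa)")
    # psi/psi_sat >= 1 when drier than air entry; clamp at saturation
    theta = layer.theta_sat * np.maximum(psi / layer.psi_sat, 1.0) ** (-1.0 / layer.b)
    return float(theta) if theta.ndim == 0 else theta


# ---------------------------------------------------------------------------
# potential evapotranspiration
# ---------------------------------------------------------------------------


def _solar_geometry(doy, lat_deg):
    lat = math.radians(lat_deg)
    dr = 1 + 0.033 * np.cos(2 * np.pi * np.asarray(doy) / 365.0)
    decl = 0.409 * np.sin(2 * np.pi * np.asarray(doy) / 365.0 - 1.39)
    cos_ws = np.clip(-math.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)  # sunset hour angle
    ra = (24 * 60 / np.pi) * _SOLAR_CONSTANT * dr * (
        ws * math.sin(lat) * np.sin(decl) + math.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    return np.maximum(ra, 0.0), ws


def day_length_hours(doy, lat_deg: float):
    """Astronomical day length in hours."""
    if not -90 <= lat_deg <= 90:
        raise ValueError("latitude out of range")
    _, ws = _solar_geometry(doy, lat_deg)
    n = 24.0 / np.pi * ws
    return float(n) if np.ndim(doy) == 0 else n


def _esat_kpa(t):
    return 0.6108 * np.exp(17.27 * np.asarray(t, dtype=float) / (np.asarray(t) + 237.3))


def pet_daily(doy, lat_deg, tmax, tmin, rh_pct, wind_ms, cloud_frac,
              correction: float = 1.2):
    """Potential evapotranspiration, mm/day (Penman-family combination).

    Radiation term uses extraterrestrial radiation (hence latitude and
    day-of-year, i.e. day length) attenuated by cloud cover; the
    aerodynamic term is scaled by daylight fraction so that PET
    vanishes during polar night.  The result is multiplied by
    ``correction`` (default 1.2, compensating systematic Penman
    underestimation in dry regions).

    Accepts scalars or aligned arrays for the daily inputs.
    """
    if not -90 <= lat_deg <= 90:
        raise ValueError("latitude out of range")
    doy = np.asarray(doy)
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    tmean = 0.5 * (tmax + tmin)
    ra, ws = _solar_geometry(doy, lat_deg)
    daylight = ws / np.pi  # fraction of a 12 h reference day in [0, 1]

    rs = (0.25 + 0.50 * (1.0 - np.asarray(cloud_frac, dtype=float))) * ra
    es = 0.5 * (_esat_kpa(tmax) + _esat_kpa(tmin))
    ea = np.asarray(rh_pct, dtype=float) / 100.0 * es
    rso = np.maximum(0.75 * ra, 1e-9)
    cloud_term = np.clip(1.35 * rs / rso - 0.35, 0.05, 1.0)
    tk4 = 0.5 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4)
    rnl = _STEFAN_BOLTZMANN * tk4 * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0))) * cloud_term
    rn = np.maximum(0.77 * rs - rnl, 0.0)

    delta = 4098.0 * _esat_kpa(tmean) / (tmean + 237.3) ** 2
    gamma = 0.066
    radiation = delta / (delta + gamma) * rn / _LATENT_HEAT
    aero = (gamma / (delta + gamma)
            * 6.43 * (1.0 + 0.536 * np.asarray(wind_ms, dtype=float))
            * np.maximum(es - ea, 0.0) / _LATENT_HEAT) * daylight
    pet = np.maximum(radiation + aero, 0.0) * correction
    return float(pet) if pet.ndim == 0 else pet


# ---------------------------------------------------------------------------
# snow
# ---------------------------------------------------------------------------


def partition_precip_snow(precip: float, tmean: float,
                          snow_threshold: float = 0.0) -> tuple[float, float]:
    """Split daily precipitation into (rain, snowfall) by mean temperature."""
    if precip < 0:
        raise ValueError("precip must be >= 0")
    if tmean < snow_threshold:
        return 0.0, precip
    return precip, 0.0


def melt_snow(swe: float, tmean: float, melt_coeff: float = 2.0,
              snow_threshold: float = 0.0) -> float:
    """Degree-day snowmelt (mm), capped by the snowpack."""
    if swe < 0:
        raise ValueError("swe must be >= 0")
    demand = melt_coeff * max(0.0, tmean - snow_threshold)
    return min(swe, demand)


# ---------------------------------------------------------------------------
# interception
# ---------------------------------------------------------------------------


def intercept(precip_liquid: float, biomass_gm2: float, litter_gm2: float,
              capacity_per_gm2: float = 0.0025) -> tuple[float, float]:
    """Canopy + litter interception of liquid precipitation.

    Storage capacity is proportional to standing biomass plus litter;
    interception is capped by both capacity and supply.  Returns
    (interception_loss, throughfall).
    """
    if min(precip_liquid, biomass_gm2, litter_gm2) < 0:
        raise ValueError("inputs must be >= 0")
    capacity = capacity_per_gm2 * (biomass_gm2 + litter_gm2)
    loss = min(precip_liquid, capacity)
    return loss, precip_liquid - loss


# ---------------------------------------------------------------------------
# infiltration / percolation
# ---------------------------------------------------------------------------


def infiltrate_and_percolate(water_in: float, theta: np.ndarray,
                             profile: SoilProfile) -> tuple[np.ndarray, np.ndarray, float]:
    """Cascading-bucket infiltration.

    Each layer fills toward field capacity; the excess percolates to the
    next layer; water leaving the bottom layer is deep drainage.  Returns
    (new_theta, percolation_out_of_each_layer_mm, deep_drainage_mm).
    Mass is conserved exactly.
    """
    if water_in < 0:
        raise ValueError("water_in must be >= 0")
    theta = theta.copy()
    n = len(profile)
    perc = np.zeros(n)
    flux = water_in
    for i, layer in enumerate(profile.layers):
        deficit = max(0.0, (layer.field_capacity - theta[i]) * layer.thickness_mm)
        taken = min(flux, deficit)
        theta[i] += taken / layer.thickness_mm
        flux -= taken
        perc[i] = flux
    return theta, perc, flux


# ---------------------------------------------------------------------------
# stress functions, evaporation and transpiration
# ---------------------------------------------------------------------------


def _swp_stress(psi, psi_wet: float, psi_dry: float):
    """Piecewise-linear 0..1 factor: 1 at/above psi_wet, 0 at/below psi_dry."""
    return np.clip((np.asarray(psi) - psi_dry) / (psi_wet - psi_dry), 0.0, 1.0)


def _group_mean_swp(theta: np.ndarray, profile: SoilProfile,
                    idx: np.ndarray) -> float:
    """SWP of the thickness-weighted mean water content over layers ``idx``."""
    w = profile.thickness_mm[idx]
    mean_theta = float(np.sum(theta[idx] * w) / np.sum(w))
    mean_layer = _effective_layer(profile, idx)
    return swp_from_theta(max(mean_theta, 1e-9), mean_layer)


def _effective_layer(profile: SoilProfile, idx: np.ndarray) -> SoilLayer:
    """Thickness-weighted 'average' layer for group-level retention."""
    w = profile.thickness_mm[idx]
    w = w / w.sum()

    def avg(attr):
        return float(np.sum(profile.array(attr)[idx] * w))

    layers = [profile.layers[i] for i in np.atleast_1d(idx)]
    return SoilLayer(
        depth_top=layers[0].depth_top, depth_bottom=layers[-1].depth_bottom,
        sand=avg("sand"), clay=avg("clay"), theta_sat=avg("theta_sat"),
        psi_sat=avg("psi_sat"), b=avg("b"),
        field_capacity=avg("field_capacity"), wilting_point=avg("wilting_point"),
    )


def bare_soil_evap(theta: np.ndarray, pet_share: float, profile: SoilProfile,
                   evap_depth_cm: float = 15.0, psi_wet: float = -0.033,
                   psi_dry: float = -15.0) -> tuple[float, np.ndarray]:
    """Bare-soil evaporation from layers within the evaporation depth.

    Demand is ``pet_share`` times a piecewise-linear stress factor of the
    surface-group SWP; extraction is proportional to each layer's water
    above the dry-limit content and never exceeds it.
    Returns (evaporation_mm, new_theta).
    """
    if pet_share < 0:
        raise ValueError("pet_share must be >= 0")
    theta = theta.copy()
    tops = profile.array("depth_top")
    idx = np.where(tops < evap_depth_cm)[0]
    if idx.size == 0 or pet_share == 0.0:
        return 0.0, theta
    psi_surface = _group_mean_swp(theta, profile, idx)
    demand = float(_swp_stress(psi_surface, psi_wet, psi_dry)) * pet_share
    avail = np.zeros(len(idx))
    for k, i in enumerate(idx):
        layer = profile.layers[i]
        theta_dry = theta_from_swp(psi_dry, layer)
        avail[k] = max(0.0, (theta[i] - theta_dry) * layer.thickness_mm)
    total_avail = avail.sum()
    evap = min(demand, total_avail)
    if evap > 0:
        take = evap * avail / total_avail
        for k, i in enumerate(idx):
            theta[i] -= take[k] / profile.layers[i].thickness_mm
    return evap, theta


def transpire(theta: np.ndarray, pet_share: float, comp: dict[str, float],
              live_fraction: dict[str, float], roots: dict[str, np.ndarray],
              critical_swp: dict[str, float], profile: SoilProfile,
              psi_wet: float = -0.05) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer, per-group transpiration.

    Potential transpiration of group g is pet_share * cover_g * live_g.
    It is distributed over layers proportionally to root fraction times a
    SWP stress factor that is 0 at/below the group's critical SWP and 1
    at the wet limit; realized uptake is additionally capped by each
    layer's water above the group's critical content.  Returns
    (uptake_mm[group, layer] as a 2-D array ordered by sorted group
    names, new_theta).
    """
    if pet_share < 0:
        raise ValueError("pet_share must be >= 0")
    theta = theta.copy()
    groups = sorted(comp)
    uptake = np.zeros((len(groups), len(profile)))
    psi = np.array([swp_from_theta(max(theta[i], 1e-9), l)
                    for i, l in enumerate(profile.layers)])
    for gi, g in enumerate(groups):
        potential = pet_share * comp[g] * live_fraction.get(g, 0.0)
        if potential <= 0:
            continue
        rf = roots[g]
        stress = _swp_stress(psi, psi_wet, critical_swp[g])
        weights = rf * stress
        demand = potential * weights  # sum <= potential since rf sums to 1
        for i, layer in enumerate(profile.layers):
            if demand[i] <= 0:
                continue
            theta_crit = theta_from_swp(critical_swp[g], layer)
            avail = max(0.0, (theta[i] - theta_crit) * layer.thickness_mm)
            take = min(demand[i], avail)
            uptake[gi, i] = take
            theta[i] -= take / layer.thickness_mm
        psi = np.array([swp_from_theta(max(theta[i], 1e-9), l)
                        for i, l in enumerate(profile.layers)])
    return uptake, theta


def hydraulic_redistribute(theta: np.ndarray, profile: SoilProfile,
                           root_density: np.ndarray, max_rate: float = 0.1,
                           conductance: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Passive root-mediated water movement along SWP gradients.

    For every layer pair, water moves from the wetter (higher psi) to the
    drier layer at conductance * |dpsi| mm/day, capped at ``max_rate`` per
    pair and limited so no layer exceeds field capacity or falls below
    wilting point.  Returns (signed per-layer flux mm, new_theta); the
    fluxes sum to zero by construction.
    """
    theta = theta.copy()
    n = len(profile)
    flux = np.zeros(n)
    psi = np.array([swp_from_theta(max(theta[i], 1e-9), l)
                    for i, l in enumerate(profile.layers)])
    for i in range(n):
        for j in range(i + 1, n):
            dpsi = psi[i] - psi[j]
            if dpsi == 0.0:
                continue
            src, dst = (i, j) if dpsi > 0 else (j, i)
            overlap = min(root_density[src], root_density[dst])
            amount = min(max_rate, conductance * abs(dpsi)) * overlap
            src_layer, dst_layer = profile.layers[src], profile.layers[dst]
            amount = min(amount,
                         max(0.0, (theta[src] - src_layer.wilting_point) * src_layer.thickness_mm),
                         max(0.0, (dst_layer.field_capacity - theta[dst]) * dst_layer.thickness_mm))
            if amount <= 0:
                continue
            theta[src] -= amount / src_layer.thickness_mm
            theta[dst] += amount / dst_layer.thickness_mm
            flux[src] -= amount
            flux[dst] += amount
    return flux, theta


# ---------------------------------------------------------------------------
# daily driver
# ---------------------------------------------------------------------------


@dataclass
class WaterBalanceParams:
    """Process parameters of the daily water balance (all configurable)."""

    pet_correction: float = 1.2
    snow_threshold_c: float = 0.0
    melt_coeff_mm_per_c: float = 2.0
    interception_capacity_per_gm2: float = 0.0025
    evap_depth_cm: float = 15.0
    evap_psi_wet_mpa: float = -0.033
    evap_psi_dry_mpa: float = -15.0
    transp_psi_wet_mpa: float = -0.05
    critical_swp_mpa: dict[str, float] = field(
        default_factory=lambda: {"shrub": -3.9, "c3": -3.5, "c4": -3.5})
    hydraulic_redistribution: bool = True
    hr_max_rate_mm: float = 0.1
    hr_conductance: float = 0.05
    cover_scale_gm2: float = 800.0  # live+litter biomass at full canopy cover
    max_cover: float = 0.9
    initial_theta: str = "field_capacity"  # or "midpoint"


@dataclass
class SimulationResult:
    """Daily state and flux trajectory of one simulation."""

    daily: pd.DataFrame  # one row per day: fluxes, swe, storage, residual
    theta: np.ndarray  # day x layer volumetric water content
    transpiration: np.ndarray  # day x layer, mm (summed over groups)
    profile: SoilProfile

    @property
    def years(self) -> np.ndarray:
        return self.daily["date"].dt.year.to_numpy()

    def annual(self, column: str, how: str = "sum") -> pd.Series:
        grouped = self.daily.groupby(self.daily["date"].dt.year)[column]
        return grouped.sum() if how == "sum" else grouped.mean()


def simulate(weather: pd.DataFrame, profile: SoilProfile, vegetation,
             latitude: float, monthly_rh: np.ndarray, monthly_wind: np.ndarray,
             monthly_cloud: np.ndarray,
             params: WaterBalanceParams | None = None) -> SimulationResult:
    """Run the daily water balance over a multi-year weather series.

    ``weather`` needs columns date, tmax, tmin, precip covering >= 2
    calendar years (the first year is conventionally discarded downstream
    as spin-up).  ``vegetation`` is a :class:`drylandsim.vegetation.Vegetation`
    bundle.  Deterministic; daily closure is recorded in the ``residual``
    column and asserted < 1e-6 mm.

    Operator order within a day: PET -> snow partition/melt ->
    interception -> infiltration/percolation -> bare-soil evaporation ->
    transpiration -> hydraulic redistribution.
    """
    params = params or WaterBalanceParams()
    if weather["date"].dt.year.nunique() < 2:
        raise ValueError("need at least 2 simulated years (first is spin-up)")

    dates = pd.DatetimeIndex(weather["date"])
    months = dates.month.to_numpy() - 1
    doy = dates.dayofyear.to_numpy()
    tmax = weather["tmax"].to_numpy(float)
    tmin = weather["tmin"].to_numpy(float)
    precip = weather["precip"].to_numpy(float)
    tmean = 0.5 * (tmax + tmin)

    pet = pet_daily(doy, latitude, tmax, tmin,
                    np.asarray(monthly_rh)[months], np.asarray(monthly_wind)[months],
                    np.asarray(monthly_cloud)[months], correction=params.pet_correction)

    groups = sorted(vegetation.composition.as_dict())
    comp = vegetation.composition.as_dict()
    live = {g: np.asarray(vegetation.monthly.live_fraction[g]) for g in groups}
    biomass = {g: np.asarray(vegetation.monthly.biomass[g]) for g in groups}
    litter = {g: np.asarray(vegetation.monthly.litter[g]) for g in groups}
    roots = {g: np.asarray(vegetation.roots[g].layer_fractions) for g in groups}
    root_density = sum(comp[g] * roots[g] for g in groups)
    critical = {g: params.critical_swp_mpa.get(g, -3.5) for g in groups}

    # monthly canopy cover from live biomass + litter
    live_biomass_m = np.array([sum(biomass[g][m] * live[g][m] * comp[g] for g in groups)
                               for m in range(12)])
    litter_m = np.array([sum(litter[g][m] * comp[g] for g in groups) for m in range(12)])
    cover_m = np.clip((live_biomass_m + 0.5 * litter_m) / params.cover_scale_gm2,
                      0.0, params.max_cover)
    standing_m = np.array([sum(biomass[g][m] * comp[g] for g in groups) for m in range(12)])

    n_days = len(weather)
    n_layers = len(profile)
    if params.initial_theta == "field_capacity":
        theta = profile.array("field_capacity").copy()
    else:
        theta = 0.5 * (profile.array("field_capacity") + profile.array("wilting_point"))

    theta_out = np.empty((n_days, n_layers))
    transp_out = np.zeros((n_days, n_layers))
    cols = {k: np.zeros(n_days) for k in
            ("rain", "snowfall", "melt", "swe", "interception", "infiltration",
             "evap", "transp", "drainage", "storage", "residual")}
    swe = 0.0
    thickness = profile.thickness_mm
    storage = float(np.sum(theta * thickness))

    for d in range(n_days):
        m = months[d]
        storage_prev, swe_prev = storage, swe
        rain, snowfall = partition_precip_snow(precip[d], tmean[d],
                                               params.snow_threshold_c)
        swe += snowfall
        melt = melt_snow(swe, tmean[d], params.melt_coeff_mm_per_c,
                         params.snow_threshold_c)
        swe -= melt
        loss, throughfall = intercept(rain, standing_m[m], litter_m[m],
                                      params.interception_capacity_per_gm2)
        water_in = throughfall + melt
        theta, _, drainage = infiltrate_and_percolate(water_in, theta, profile)
        pet_avail = max(0.0, pet[d] - loss)
        evap_share = (1.0 - cover_m[m]) * pet_avail
        transp_share = cover_m[m] * pet_avail
        evap, theta = bare_soil_evap(theta, evap_share, profile,
                                     params.evap_depth_cm,
                                     params.evap_psi_wet_mpa,
                                     params.evap_psi_dry_mpa)
        live_today = {g: float(live[g][m]) for g in groups}
        uptake, theta = transpire(theta, transp_share, comp, live_today, roots,
                                  critical, profile, params.transp_psi_wet_mpa)
        if params.hydraulic_redistribution:
            _, theta = hydraulic_redistribute(theta, profile, root_density,
                                              params.hr_max_rate_mm,
                                              params.hr_conductance)
        transp_layer = uptake.sum(axis=0)
        transp_total = float(transp_layer.sum())
        storage = float(np.sum(theta * thickness))
        residual = (precip[d] + (swe_prev - swe) + (storage_prev - storage)
                    - loss - evap - transp_total - drainage)

        theta_out[d] = theta
        transp_out[d] = transp_layer
        cols["rain"][d] = rain
        cols["snowfall"][d] = snowfall
        cols["melt"][d] = melt
        cols["swe"][d] = swe
        cols["interception"][d] = loss
        cols["infiltration"][d] = water_in - drainage
        cols["evap"][d] = evap
        cols["transp"][d] = transp_total
        cols["drainage"][d] = drainage
        cols["storage"][d] = storage
        cols["residual"][d] = residual
        if abs(residual) > 1e-6:
            raise RuntimeError(f"water balance closure violated on day {d}: "
                               f"residual={residual:.3e} mm")

    daily = pd.DataFrame({"date": dates, "precip": precip, "tmax": tmax,
                          "tmin": tmin, "pet": pet, **cols})
    return SimulationResult(daily=daily, theta=theta_out,
                            transpiration=transp_out, profile=profile)
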