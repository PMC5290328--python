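"""Potential vegetation from cell climate: functional-group composition
(shrubs, C3 grasses, C4 grasses), monthly biomass and phenology, and
root-distribution profiles.

The composition and phenology coefficients are configurable; the
defaults are chosen to satisfy the directional responses the analysis
relies on (C4 share grows with warm-season temperature and
precipitation, C3 share with the winter-precipitation fraction, biomass
with MAP, growing-season length with temperature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .water_balance import SoilProfile

__all__ = [
    "GROUPS",
    "VegComposition",
    "MonthlyVegetation",
    "RootProfile",
    "CompositionCoefficients",
    "PhenologyParams",
    "Vegetation",
    "potential_composition",
    "monthly_biomass_phenology",
    "rooting_profile",
    "soil_depth_from_roots",
    "build_vegetation",
    "DEFAULT_BETA",
]

GROUPS = ("shrub", "c3", "c4")

#: Jackson-type root-decay parameters per functional group (per cm depth)
DEFAULT_BETA = {"shrub": 0.978, "c3": 0.952, "c4": 0.943}


@dataclass(frozen=True)
class VegComposition:
    """Relative cover of the three functional groups (sums to 1)."""

    f_shrub: float
    f_c3: float
    f_c4: float

    def __post_init__(self) -> None:
        fracs = (self.f_shrub, self.f_c3, self.f_c4)
        if any(f < -1e-12 or f > 1 + 1e-12 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"shrub": self.f_shrub, "c3": self.f_c3, "c4": self.f_c4}


@dataclass(frozen=True)
class MonthlyVegetation:
    """Per-group 12-month schedules of biomass, live fraction and litter."""

    biomass: dict[str, np.ndarray]  # g/m2
    live_fraction: dict[str, np.ndarray]  # [0, 1]
    litter: dict[str, np.ndarray]  # g/m2


@dataclass(frozen=True)
class RootProfile:
    """Per-layer root fractions of one group over a soil profile."""

    layer_fractions: np.ndarray  # sums to 1
    beta: float
    max_root_depth: float  # cm


@dataclass(frozen=True)
class CompositionCoefficients:
    """Coefficients of the climate -> composition relationships."""

    c4_temp_base: float = 10.0  # degC; warm-season temps above this favour C4
    c4_temp_slope: float = 1.0
    c4_precip_slope: float = 0.02  # per mm warm-season precipitation
    c3_base: float = 10.0
    c3_winter_slope: float = 30.0  # per unit winter-precip fraction
    shrub_base: float = 10.0
    shrub_aridity_slope: float = 20.0  # favours shrubs at low MAP
    shrub_map_scale: float = 500.0


@dataclass(frozen=True)
class PhenologyParams:
    """Biomass/phenology modulation parameters."""

    growth_temp_c: float = 4.0  # live fraction ramps up above this
    full_growth_temp_c: float = 10.0
    biomass_per_mm_map: float = 1.0  # g/m2 per mm MAP
    biomass_cap_gm2: float = 1500.0
    litter_fraction: float = 0.5
    dormant_standing_fraction: float = 0.4


def potential_composition(mat: float, map_mm: float,
                          winter_precip_fraction: float,
                          warm_season_temp: float,
                          warm_season_precip: float = 0.0,
                          coeffs: CompositionCoefficients | None = None,
                          ) -> VegComposition:
    """Potential shrub/C3/C4 composition from climate normals.

    Scores: the C4 score is non-decreasing in warm-season temperature and
    precipitation; the C3 score is non-decreasing in the
    winter-precipitation fraction; the shrub score depends only on MAP.
    Fractions are the normalized scores.
    """
    c = coeffs or CompositionCoefficients()
    s_c4 = (max(0.0, warm_season_temp - c.c4_temp_base) * c.c4_temp_slope
            + max(0.0, warm_season_precip) * c.c4_precip_slope)
    s_c3 = c.c3_base + c.c3_winter_slope * min(max(winter_precip_fraction, 0.0), 1.0)
    s_shrub = c.shrub_base + c.shrub_aridity_slope * math.exp(
        -max(map_mm, 0.0) / c.shrub_map_scale)
    total = s_shrub + s_c3 + s_c4
    return VegComposition(f_shrub=s_shrub / total, f_c3=s_c3 / total,
                          f_c4=s_c4 / total)


def monthly_biomass_phenology(comp: VegComposition, monthly_temp,
                              map_mm: float,
                              params: PhenologyParams | None = None,
                              ) -> MonthlyVegetation:
    """12-month biomass/live-fraction/litter schedule per group.

    Live fraction ramps linearly from 0 at ``growth_temp_c`` to 1 at
    ``full_growth_temp_c`` of the monthly mean temperature, so warmer
    normals widen the growing window.  Peak biomass is piecewise-linear
    in MAP with a cap; litter is a fixed fraction of peak biomass.
    """
    p = params or PhenologyParams()
    t = np.asarray(monthly_temp, dtype=float)
    if t.shape != (12,):
        raise ValueError("need 12 monthly mean temperatures")
    live = np.clip((t - p.growth_temp_c)
                   / (p.full_growth_temp_c - p.growth_temp_c), 0.0, 1.0)
    peak = min(p.biomass_cap_gm2, p.biomass_per_mm_map * max(map_mm, 0.0))
    standing = peak * (p.dormant_standing_fraction
                       + (1.0 - p.dormant_standing_fraction) * live)
    litter = np.full(12, p.litter_fraction * peak)
    biomass = {g: standing.copy() for g in GROUPS}
    live_fraction = {g: live.copy() for g in GROUPS}
    litter_d = {g: litter.copy() for g in GROUPS}
    # C4 grasses need warmer months: shift their ramp up by 4 degC
    live_fraction["c4"] = np.clip(
        (t - p.growth_temp_c - 4.0) / (p.full_growth_temp_c - p.growth_temp_c),
        0.0, 1.0)
    return MonthlyVegetation(biomass=biomass, live_fraction=live_fraction,
                             litter=litter_d)


def rooting_profile(profile: SoilProfile, beta: float) -> RootProfile:
    """Root fractions per layer from the cumulative distribution
    1 - beta**depth_cm, renormalized over the profile."""
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    weights = np.array([beta ** l.depth_top - beta ** l.depth_bottom
                        for l in profile.layers])
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate root distribution")
    return RootProfile(layer_fractions=weights / total, beta=beta,
                       max_root_depth=profile.total_depth_cm)


def soil_depth_from_roots(max_root_depth: float,
                          reference_depth_cm: float | None = None) -> float:
    """Soil depth as 95% of the maximum root depth, rounded to the nearest
    50 cm interval (ties rounded up).  When a reference soil depth of at
    most 1 m is available it is used directly instead."""
    if max_root_depth <= 0:
        raise ValueError("max_root_depth must be > 0")
    if reference_depth_cm is not None and reference_depth_cm <= 100.0:
        return float(reference_depth_cm)
    target = 0.95 * max_root_depth
    return max(50.0, 50.0 * math.floor(target / 50.0 + 0.5))


@dataclass(frozen=True)
class Vegetation:
    """Bundle consumed by the water-balance simulator."""

    composition: VegComposition
    monthly: MonthlyVegetation
    roots: dict[str, RootProfile]
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))


def build_vegetation(normals, profile: SoilProfile,
                     beta: dict[str, float] | None = None,
                     coeffs: CompositionCoefficients | None = None,
                     phen: PhenologyParams | None = None) -> Vegetation:
    """Derive the full vegetation bundle for a cell from its monthly
    normals (a :class:`drylandsim.synthetic_data.MonthlyNormals`)."""
    beta = dict(beta or DEFAULT_BETA)
    t = np.asarray(normals.monthly_temp)
    p = np.asarray(normals.monthly_precip)
    warm_idx = np.argsort(t)[-3:]
    cold_idx = np.argsort(t)[:3]
    map_mm = float(p.sum())
    winter_frac = float(p[cold_idx].sum() / map_mm) if map_mm > 0 else 0.0
    comp = potential_composition(
        mat=normals.mat, map_mm=map_mm, winter_precip_fraction=winter_frac,
        warm_season_temp=float(t[warm_idx].mean()),
        warm_season_precip=float(p[warm_idx].sum()), coeffs=coeffs)
    monthly = monthly_biomass_phenology(comp, t, map_mm, phen)
    roots = {g: rooting_profile(profile, beta[g]) for g in GROUPS}
    return Vegetation(composition=comp, monthly=monthly, roots=roots, beta=beta)
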