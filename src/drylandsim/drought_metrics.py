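"""Ecological-drought response variables from daily simulation output.

DDGP0 / DDGP20: longest annual run of consecutive snow-free, frost-free
days with depth-group soil water potential continuously below -3.0 MPa,
for the surface (0-20 cm) and deep (> 20 cm) layer groups.  T20/T:
annual fraction of transpiration extracted below 20 cm.  Annual values
are aggregated by mean and standard deviation after discarding the
spin-up year(s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .water_balance import SoilProfile, _effective_layer, swp_from_theta

__all__ = [
    "DroughtMetrics",
    "eligible_days",
    "layer_group_swp",
    "longest_run",
    "ddgp",
    "deep_transp_fraction",
    "aggregate_years",
    "compute_drought_metrics",
    "SWP_DROUGHT_THRESHOLD_MPA",
    "DEPTH_SPLIT_CM",
]

SWP_DROUGHT_THRESHOLD_MPA = -3.0
DEPTH_SPLIT_CM = 20.0


@dataclass(frozen=True)
class DroughtMetrics:
    """Aggregated drought metrics of one (cell, climate condition)."""

    ddgp0_mean: float
    ddgp0_sd: float
    ddgp20_mean: float
    ddgp20_sd: float
    t20_mean: float
    t20_sd: float


def eligible_days(tmin, swe, frost_threshold: float = 0.0) -> np.ndarray:
    """Snow-free AND frost-free flag per day: swe == 0 and
    tmin > frost_threshold."""
    tmin = np.asarray(tmin, dtype=float)
    swe = np.asarray(swe, dtype=float)
    if tmin.shape != swe.shape:
        raise ValueError("tmin and swe must be aligned")
    return (swe <= 0.0) & (tmin > frost_threshold)


def _group_indices(profile: SoilProfile, depth_split: float) -> tuple[np.ndarray, np.ndarray]:
    tops = profile.array("depth_top")
    bottoms = profile.array("depth_bottom")
    surface = np.where(bottoms <= depth_split)[0]
    deep = np.where(tops >= depth_split)[0]
    if len(surface) + len(deep) != len(profile):
        raise ValueError(f"profile layers must respect the {depth_split} cm boundary")
    return surface, deep


def layer_group_swp(theta: np.ndarray, profile: SoilProfile,
                    depth_split: float = DEPTH_SPLIT_CM,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Daily (surface, deep) group soil water potential, MPa.

    ``theta`` is (n_days, n_layers).  Group SWP is the retention-curve
    potential of the thickness-weighted mean water content, evaluated
    with thickness-weighted retention parameters.  A group with no
    layers yields NaN.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    surface, deep = _group_indices(profile, depth_split)
    n_days = theta.shape[0]

    def group_psi(idx: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            return np.full(n_days, np.nan)
        w = profile.thickness_mm[idx]
        mean_theta = theta[:, idx] @ w / w.sum()
        eff = _effective_layer(profile, idx)
        return swp_from_theta(np.maximum(mean_theta, 1e-9), eff)

    return group_psi(surface), group_psi(deep)


def longest_run(flags) -> int:
    """Length of the longest run of consecutive True values."""
    best = cur = 0
    for f in np.asarray(flags, dtype=bool):
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def ddgp(group_swp, eligible, years,
         threshold: float = SWP_DROUGHT_THRESHOLD_MPA) -> pd.Series:
    """Per-year drought duration during growing periods.

    For each calendar year: the longest run of consecutive days that are
    simultaneously eligible (snow-free, frost-free) and have group SWP
    strictly below ``threshold``.  Runs do not cross year boundaries.
    Years whose SWP is entirely NaN (no layers in the group) yield NaN.
    """
    swp = np.asarray(group_swp, dtype=float)
    elig = np.asarray(eligible, dtype=bool)
    years = np.asarray(years)
    if not (len(swp) == len(elig) == len(years)):
        raise ValueError("series must be aligned")
    out = {}
    for y in np.unique(years):
        sel = years == y
        if np.all(np.isnan(swp[sel])):
            out[int(y)] = float("nan")
        else:
            qualifying = elig[sel] & (swp[sel] < threshold)
            out[int(y)] = float(longest_run(qualifying))
    return pd.Series(out, name="ddgp")


def deep_transp_fraction(transp_layer: np.ndarray, profile: SoilProfile,
                         years, depth_split: float = DEPTH_SPLIT_CM) -> pd.Series:
    """Per-year T20/T: fraction of annual transpiration taken up below
    ``depth_split``.  NaN when annual total transpiration is zero."""
    transp = np.atleast_2d(np.asarray(transp_layer, dtype=float))
    years = np.asarray(years)
    if transp.shape[0] != len(years):
        raise ValueError("series must be aligned")
    _, deep = _group_indices(profile, depth_split)
    out = {}
    for y in np.unique(years):
        sel = years == y
        total = float(transp[sel].sum())
        if total <= 0:
            out[int(y)] = float("nan")
        else:
            out[int(y)] = float(transp[np.ix_(sel, deep)].sum()) / total
    return pd.Series(out, name="t20_over_t")


def aggregate_years(per_year, spin_up: int = 1) -> tuple[float, float]:
    """Mean and (sample) standard deviation over years after discarding the
    first ``spin_up`` year(s)."""
    values = np.asarray(per_year, dtype=float)
    if len(values) < spin_up + 1:
        raise ValueError("need at least spin_up + 1 years")
    kept = values[spin_up:]
    kept = kept[~np.isnan(kept)]
    if kept.size == 0:
        return float("nan"), float("nan")
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return mean, sd


def compute_drought_metrics(result, spin_up: int = 1,
                            threshold: float = SWP_DROUGHT_THRESHOLD_MPA,
                            depth_split: float = DEPTH_SPLIT_CM,
                            frost_threshold: float = 0.0) -> DroughtMetrics:
    """All drought metrics from a water-balance
    :class:`~drylandsim.water_balance.SimulationResult`."""
    years = result.years
    elig = eligible_days(result.daily["tmin"].to_numpy(float),
                         result.daily["swe"].to_numpy(float), frost_threshold)
    surf_swp, deep_swp = layer_group_swp(result.theta, result.profile, depth_split)
    ddgp0 = ddgp(surf_swp, elig, years, threshold)
    ddgp20 = ddgp(deep_swp, elig, years, threshold)
    t20 = deep_transp_fraction(result.transpiration, result.profile, years,
                               depth_split)
    m0, s0 = aggregate_years(ddgp0.to_numpy(), spin_up)
    m20, s20 = aggregate_years(ddgp20.to_numpy(), spin_up)
    mt, st = aggregate_years(t20.to_numpy(), spin_up)
    return DroughtMetrics(ddgp0_mean=m0, ddgp0_sd=s0, ddgp20_mean=m20,
                          ddgp20_sd=s20, t20_mean=mt, t20_sd=st)
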