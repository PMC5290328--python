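"""Summary and diagnostic statistics of the simulation experiment.

Regional two-step GCM summaries (per-GCM statistic over member cells,
then median and min-max range across GCMs), uniquely-attributable
variance partitioning with additive main-effect models, the one-parameter
Budyko-family curve F = 1 + x - (1 + x**omega)**(1/omega) with
least-squares omega fitting, and the symmetric agreement index lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "RegionalSummary",
    "BudykoFit",
    "regional_summary",
    "variance_partition",
    "fuh_curve",
    "fit_omega",
    "duveiller_lambda",
]


@dataclass(frozen=True)
class RegionalSummary:
    """Two-step GCM summary of one variable over one region/zone."""

    region: str
    zone: str
    variable: str
    median: float  # median of per-GCM summary statistics
    gcm_min: float
    gcm_max: float
    n_gcm: int
    per_gcm: dict[str, float]


def regional_summary(df: pd.DataFrame, value_col: str, region: str, zone: str,
                     stat: str = "median") -> RegionalSummary:
    """Two-step summary: per-GCM ``stat`` over that GCM's member cells of
    (region, zone), then median and min-max range across the GCM values.

    ``df`` needs columns cell, gcm, region, zone and ``value_col``; zone
    membership is per-GCM (zones differ among GCMs).  GCMs with no member
    cells contribute a missing value and are excluded from step 2 (with a
    warning).
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    required = {"cell", "gcm", "region", "zone", value_col}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    per_gcm: dict[str, float] = {}
    for g, sub in df.groupby("gcm"):
        members = sub[(sub["region"] == region) & (sub["zone"] == zone)]
        if members.empty:
            per_gcm[str(g)] = float("nan")
            warnings.warn(f"GCM {g} has no member cells in {region}/{zone}")
        else:
            v = members[value_col].to_numpy(float)
            per_gcm[str(g)] = float(np.median(v) if stat == "median" else v.mean())
    values = np.array([v for v in per_gcm.values() if not np.isnan(v)])
    if values.size == 0:
        med = lo = hi = float("nan")
    else:
        med, lo, hi = float(np.median(values)), float(values.min()), float(values.max())
    return RegionalSummary(region=region, zone=zone, variable=value_col,
                           median=med, gcm_min=lo, gcm_max=hi,
                           n_gcm=int(values.size), per_gcm=per_gcm)


def _additive_ss(y: np.ndarray, design: pd.DataFrame, factors: list[str]) -> float:
    """Model sum of squares of an additive (main effects only) OLS fit."""
    if not factors:
        return 0.0
    dummies = pd.get_dummies(design[factors].astype(str), drop_first=True)
    x = np.column_stack([np.ones(len(y))] + ([dummies.to_numpy(float)]
                                             if dummies.shape[1] else []))
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    return float(np.sum((fitted - y.mean()) ** 2))


def variance_partition(df: pd.DataFrame, value_col: str,
                       factors: list[str]) -> dict[str, float]:
    """Uniquely attributable variance components, percent of total.

    For each factor f: unique(f) = SS(additive model with all factors)
    minus SS(additive model without f), as a percentage of the total sum
    of squares.  Everything not uniquely attributable (shared between
    factors plus residual) is reported under ``"shared_residual"``, so
    the components sum to 100 exactly.  Constant data yields an all-zero
    partition with a warning.
    """
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"missing factor column {f!r}")
    y = df[value_col].to_numpy(float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        warnings.warn("constant response: degenerate variance partition")
        out = {f: 0.0 for f in factors}
        out["shared_residual"] = 0.0
        return out
    usable = [f for f in factors if df[f].nunique() > 1]
    ss_full = _additive_ss(y, df, usable)
    out = {}
    for f in factors:
        if f not in usable:
            out[f] = 0.0
            continue
        ss_without = _additive_ss(y, df, [g for g in usable if g != f])
        out[f] = 100.0 * (ss_full - ss_without) / ss_total
    out["shared_residual"] = 100.0 - sum(out.values())
    return out


def fuh_curve(ai_b, omega: float):
    """Budyko-family curve F = 1 + x - (1 + x**omega)**(1/omega).

    x is the Budyko aridity index PET/P (>= 0); F estimates AET/P.
    F(0, omega) = 0 and F(x, 1) = 0 identically; for omega >= 1,
    0 <= F <= min(1, x).
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    x = np.asarray(ai_b, dtype=float)
    if np.any(x < 0):
        raise ValueError("ai_b must be >= 0")
    f = 1.0 + x - (1.0 + x ** omega) ** (1.0 / omega)
    return float(f) if f.ndim == 0 else f


@dataclass(frozen=True)
class BudykoFit:
    """Least-squares fit of the curve parameter omega for one region."""

    omega: float
    sse: float
    n_cells: int
    region: str = ""


def fit_omega(aet, pet, p, region: str = "",
              bounds: tuple[float, float] = (1.0, 20.0)) -> BudykoFit:
    """Fit omega by minimizing the SSE between F = AET/P and the curve at
    x = PET/P across cells (deterministic bounded scalar minimization).

    omega <= 1 is non-physical (the curve is identically 0 at omega = 1),
    so the search is confined to (1, 20] by default.
    """
    aet = np.asarray(aet, dtype=float)
    pet = np.asarray(pet, dtype=float)
    p = np.asarray(p, dtype=float)
    if not (len(aet) == len(pet) == len(p)):
        raise ValueError("aet, pet, p must be aligned")
    if len(aet) < 3:
        raise ValueError("need >= 3 cells")
    if np.any(p <= 0):
        raise ValueError("p must be > 0")
    x = pet / p
    f_obs = aet / p
    if np.ptp(x) == 0 and np.ptp(f_obs) == 0:
        warnings.warn("degenerate identical points: flat objective")

    def sse(w: float) -> float:
        return float(np.sum((f_obs - fuh_curve(x, w)) ** 2))

    lo, hi = bounds
    res = minimize_scalar(sse, bounds=(lo + 1e-9, hi), method="bounded",
                          options={"xatol": 1e-10})
    return BudykoFit(omega=float(res.x), sse=float(res.fun),
                     n_cells=len(aet), region=region)


def duveiller_lambda(x, y) -> float:
    """Symmetric agreement index in [0, 1].

    lambda = 1 - MSD / (var_x + var_y + (mean_x - mean_y)**2 + kappa)
    with kappa = 2 |cov(x, y)| when the correlation is negative, else 0
    (population variances/covariance).  1 iff the series are identical;
    symmetric; penalizes systematic and unsystematic deviation.  Returns
    NaN when both series are constant (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 2:
        raise ValueError("need length >= 2")
    var_x = float(np.var(x))
    var_y = float(np.var(y))
    if var_x == 0.0 and var_y == 0.0:
        if float(x.mean()) == float(y.mean()):
            return float("nan")
        # constant series with different levels: pure systematic bias
        return 0.0
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    kappa = 2.0 * abs(cov) if cov < 0 else 0.0
    msd = float(np.mean((x - y) ** 2))
    denom = var_x + var_y + (float(x.mean()) - float(y.mean())) ** 2 + kappa
    # clamp float roundoff at the 0/1 boundaries
    return min(1.0, max(0.0, 1.0 - msd / denom))
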