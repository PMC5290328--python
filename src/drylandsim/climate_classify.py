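"""Climatological classification of temperate drylands.

A cell is a temperate dryland when all four criteria hold:
MAT > 0 degC, Trewartha group D (4-7 months with mean temperature
>= 10 degC), UNEP aridity index 0.05 <= AI < 0.5 (AI = MAP/PET), and
maximum sand fraction < 0.90.  Also provides shift zones between climate
conditions, per-GCM agreement histograms, the warm/wet-season overlap
and winter precipitation descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TREWARTHA_GROUPS",
    "CellClassification",
    "AgreementHistogram",
    "trewartha_group",
    "aridity_index",
    "aridity_class",
    "classify_temperate_dryland",
    "classify_shift_zone",
    "attribute_shift",
    "gcm_agreement",
    "warm_wet_overlap",
    "winter_precipitation",
    "AI_MIN",
    "AI_MAX",
    "SAND_LIMIT",
]

TREWARTHA_GROUPS = ("tropical", "subtropical", "temperate_D", "boreal", "other")
SHIFT_ZONES = ("contracting", "stable", "expanding", "outside")

AI_MIN = 0.05
AI_MAX = 0.5
SAND_LIMIT = 0.90


def trewartha_group(monthly_mean_temps) -> str:
    """Trewartha climate group from 12 monthly mean temperatures.

    tropical: all 12 months >= 18 degC (checked first); otherwise by the
    count of months with mean temperature >= 10 degC: >=8 subtropical,
    4-7 temperate_D, 1-3 boreal, 0 other.  Comparisons use full floating
    precision.
    """
    t = np.asarray(monthly_mean_temps, dtype=float)
    if t.shape != (12,):
        raise ValueError("need exactly 12 monthly mean temperatures")
    if np.all(t >= 18.0):
        return "tropical"
    n_warm = int(np.sum(t >= 10.0))
    if n_warm >= 8:
        return "subtropical"
    if n_warm >= 4:
        return "temperate_D"
    if n_warm >= 1:
        return "boreal"
    return "other"


def aridity_index(map_mm: float, pet_mm: float) -> float:
    """UNEP aridity index MAP/PET (both mm/yr)."""
    if pet_mm <= 0:
        raise ValueError("pet must be > 0")
    if map_mm < 0:
        raise ValueError("map must be >= 0")
    return map_mm / pet_mm


def aridity_class(ai: float) -> str:
    """UNEP aridity class name for an aridity index value."""
    if ai < 0:
        raise ValueError("ai must be >= 0")
    if ai < 0.05:
        return "hyper-arid"
    if ai < 0.2:
        return "arid"
    if ai < 0.5:
        return "semiarid"
    if ai < 0.65:
        return "sub-humid"
    return "humid"


@dataclass(frozen=True)
class CellClassification:
    """Classification record for one cell under one climate condition."""

    mat: float
    map: float
    pet: float
    ai: float
    trewartha_group: str
    sand_max: float
    is_temperate_dryland: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def classify_temperate_dryland(mat: float, monthly_mean_temps, map_mm: float,
                               pet_mm: float, sand_max: float,
                               ai_min: float = AI_MIN, ai_max: float = AI_MAX,
                               sand_limit: float = SAND_LIMIT) -> CellClassification:
    """Evaluate the four temperate-dryland criteria.

    Aridity bounds are left-closed, right-open: ai_min <= AI < ai_max.
    ``reasons`` lists every failed criterion ("MAT", "trewartha",
    "aridity", "sand"); empty when the cell qualifies.
    """
    group = trewartha_group(monthly_mean_temps)
    ai = aridity_index(map_mm, pet_mm)
    reasons: list[str] = []
    if not mat > 0.0:
        reasons.append("MAT")
    if group != "temperate_D":
        reasons.append("trewartha")
    if not (ai_min <= ai < ai_max):
        reasons.append("aridity")
    if not sand_max < sand_limit:
        reasons.append("sand")
    return CellClassification(mat=mat, map=map_mm, pet=pet_mm, ai=ai,
                              trewartha_group=group, sand_max=sand_max,
                              is_temperate_dryland=not reasons,
                              reasons=tuple(reasons))


def classify_shift_zone(current: bool, future: bool) -> str:
    """Shift zone from the (current, future) dryland flags:
    (T,F) contracting, (T,T) stable, (F,T) expanding, (F,F) outside."""
    if current and not future:
        return "contracting"
    if current and future:
        return "stable"
    if future:
        return "expanding"
    return "outside"


def attribute_shift(current: CellClassification,
                    future: CellClassification) -> tuple[str, ...]:
    """Name the criteria that flipped between two classifications.

    Returns an empty tuple for cells that did not change dryland status.
    Climate-group transitions are reported as "climate: a->b" and aridity
    class transitions as "aridity: a->b"; MAT and sand flips are named
    directly.
    """
    if current.is_temperate_dryland == future.is_temperate_dryland:
        return ()
    out: list[str] = []
    if current.trewartha_group != future.trewartha_group:
        out.append(f"climate: {current.trewartha_group}->{future.trewartha_group}")
    cur_ac, fut_ac = aridity_class(current.ai), aridity_class(future.ai)
    if cur_ac != fut_ac:
        out.append(f"aridity: {cur_ac}->{fut_ac}")
    if (current.mat > 0) != (future.mat > 0):
        out.append("MAT")
    if (current.sand_max < SAND_LIMIT) != (future.sand_max < SAND_LIMIT):
        out.append("sand")
    return tuple(out)


@dataclass(frozen=True)
class AgreementHistogram:
    """Cell counts per GCM-agreement level (0..n_gcm)."""

    counts: np.ndarray  # length n_gcm + 1
    per_cell: np.ndarray  # agreement level per cell

    @property
    def n_gcm(self) -> int:
        return len(self.counts) - 1


def gcm_agreement(flags) -> AgreementHistogram:
    """Agreement histogram from a (n_cells, n_gcm) boolean array.

    Per cell the agreement level is the number of GCMs whose flag is
    true; the histogram counts cells per level and sums to the number of
    cells.  Ragged input raises.
    """
    try:
        arr = np.asarray(flags, dtype=bool)
    except ValueError as exc:
        raise ValueError("ragged per-GCM flags") from exc
    if arr.ndim != 2:
        raise ValueError("flags must be a 2-D (cells x GCMs) array")
    per_cell = arr.sum(axis=1)
    n_gcm = arr.shape[1]
    counts = np.bincount(per_cell, minlength=n_gcm + 1)
    return AgreementHistogram(counts=counts, per_cell=per_cell)


def warm_wet_overlap(monthly_temp, monthly_precip) -> float:
    """Pearson correlation of the 12 monthly temperatures and precipitation
    totals; +1 means the wet and warm seasons coincide.  Returns NaN when
    either series is constant (correlation undefined)."""
    t = np.asarray(monthly_temp, dtype=float)
    p = np.asarray(monthly_precip, dtype=float)
    if t.shape != (12,) or p.shape != (12,):
        raise ValueError("need 12 monthly values each")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        return float("nan")
    return float(np.corrcoef(t, p)[0, 1])


def winter_precipitation(monthly_precip, hemisphere: str) -> float:
    """Cold-season precipitation: Dec+Jan+Feb in the northern hemisphere,
    Jun+Jul+Aug in the southern."""
    p = np.asarray(monthly_precip, dtype=float)
    if p.shape != (12,):
        raise ValueError("need 12 monthly values")
    if hemisphere not in ("north", "south"):
        raise ValueError("hemisphere must be 'north' or 'south'")
    months = (12, 1, 2) if hemisphere == "north" else (6, 7, 8)
    return float(sum(p[m - 1] for m in months))
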