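"""Hybrid-delta construction of future daily forcing.

Monthly GCM change signals (additive temperature deltas, multiplicative
precipitation ratios) are derived from paired historical/future monthly
GCM series and applied to an observed daily record, preserving its day
count and wet-day pattern.  Two modes: "mean" (per-month mean change)
and "quantile" (empirical quantile mapping of each observed month into
the GCM distributions; 17 quantile bins by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyDeltaSet",
    "QuantileDeltaSet",
    "derive_deltas",
    "apply_deltas",
    "DEFAULT_RATIO_CAP",
    "DEFAULT_N_BINS",
]

DEFAULT_RATIO_CAP = 5.0
DEFAULT_N_BINS = 17


@dataclass(frozen=True)
class MonthlyDeltaSet:
    """Per-calendar-month mean change signal of one GCM/RCP."""

    temp_delta: tuple[float, ...]  # 12 additive deltas, deg C
    precip_ratio: tuple[float, ...]  # 12 multiplicative ratios, > 0
    gcm_label: str = "GCM"
    rcp_label: str = "RCP"

    def __post_init__(self) -> None:
        if len(self.temp_delta) != 12 or len(self.precip_ratio) != 12:
            raise ValueError("need 12 monthly entries each")
        if any(r <= 0 for r in self.precip_ratio):
            raise ValueError("precip ratios must be strictly positive")


@dataclass(frozen=True)
class QuantileDeltaSet:
    """Per-month quantile tables for hybrid-delta quantile mapping.

    ``hist_temp[m]``/``fut_temp[m]`` are the quantile values (at the
    probabilities in ``probs``) of calendar month m+1 in the historical
    and future GCM series; likewise for precipitation.
    """

    probs: np.ndarray
    hist_temp: np.ndarray  # (12, n_bins)
    fut_temp: np.ndarray
    hist_precip: np.ndarray
    fut_precip: np.ndarray
    ratio_cap: float = DEFAULT_RATIO_CAP
    gcm_label: str = "GCM"
    rcp_label: str = "RCP"

    def temp_delta_at(self, month: int, observed: float) -> float:
        """Temperature delta at the quantile of ``observed`` within the
        month's historical distribution (month is 1-based)."""
        h = self.hist_temp[month - 1]
        q = np.interp(observed, h, self.probs)
        return float(np.interp(q, self.probs, self.fut_temp[month - 1])
                     - np.interp(q, self.probs, h))

    def precip_ratio_at(self, month: int, observed: float) -> float:
        """Precipitation ratio at the matched quantile, capped."""
        h = self.hist_precip[month - 1]
        q = np.interp(observed, h, self.probs)
        hist_v = float(np.interp(q, self.probs, h))
        fut_v = float(np.interp(q, self.probs, self.fut_precip[month - 1]))
        if hist_v <= 0:
            return self.ratio_cap if fut_v > 0 else 1.0
        return float(min(fut_v / hist_v, self.ratio_cap))


def _monthly_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"year", "month", "temp", "precip"}
    if not required.issubset(df.columns):
        raise ValueError(f"monthly series needs columns {sorted(required)}")
    return df


def derive_deltas(gcm_hist: pd.DataFrame, gcm_fut: pd.DataFrame,
                  mode: str = "quantile", n_bins: int = DEFAULT_N_BINS,
                  ratio_cap: float = DEFAULT_RATIO_CAP, min_years: int = 20,
                  gcm_label: str = "GCM", rcp_label: str = "RCP"):
    """Derive the monthly change signal from paired GCM monthly series.

    Both inputs need columns year, month, temp, precip covering at least
    ``min_years`` years.  ``mode="mean"`` returns a
    :class:`MonthlyDeltaSet` (future-minus-historical monthly mean
    temperature, future/historical monthly mean precipitation ratio,
    capped); ``mode="quantile"`` returns a :class:`QuantileDeltaSet`.
    """
    gcm_hist, gcm_fut = _monthly_table(gcm_hist), _monthly_table(gcm_fut)
    for name, df in (("historical", gcm_hist), ("future", gcm_fut)):
        if df["year"].nunique() < min_years:
            raise ValueError(f"{name} GCM series must cover >= {min_years} years")
    if mode == "mean":
        hm = gcm_hist.groupby("month")[["temp", "precip"]].mean()
        fm = gcm_fut.groupby("month")[["temp", "precip"]].mean()
        deltas, ratios = [], []
        for m in range(1, 13):
            deltas.append(float(fm.loc[m, "temp"] - hm.loc[m, "temp"]))
            hp, fp = float(hm.loc[m, "precip"]), float(fm.loc[m, "precip"])
            if hp <= 0:
                ratios.append(ratio_cap if fp > 0 else 1.0)
            else:
                ratios.append(min(fp / hp, ratio_cap))
        return MonthlyDeltaSet(tuple(deltas), tuple(ratios), gcm_label, rcp_label)
    if mode == "quantile":
        probs = np.linspace(0.0, 1.0, n_bins)
        tables = {}
        for key, df, col in (("hist_temp", gcm_hist, "temp"),
                             ("fut_temp", gcm_fut, "temp"),
                             ("hist_precip", gcm_hist, "precip"),
                             ("fut_precip", gcm_fut, "precip")):
            tables[key] = np.stack([
                np.quantile(df.loc[df["month"] == m, col].to_numpy(float), probs)
                for m in range(1, 13)])
        return QuantileDeltaSet(probs=probs, ratio_cap=ratio_cap,
                                gcm_label=gcm_label, rcp_label=rcp_label,
                                **tables)
    raise ValueError("mode must be 'mean' or 'quantile'")


def apply_deltas(weather: pd.DataFrame, deltas) -> pd.DataFrame:
    """Apply a monthly change signal to a daily series.

    Temperature deltas shift tmax and tmin additively; precipitation
    ratios scale daily amounts multiplicatively, so the day count and
    wet-day pattern are preserved.  With a :class:`QuantileDeltaSet` the
    delta/ratio of each observed (year, month) is looked up at the
    quantile its monthly mean temperature / total precipitation occupies
    in the GCM historical distribution.  A zero/unit signal returns the
    input values bit-exactly.
    """
    out = weather.copy()
    dates = pd.DatetimeIndex(out["date"])
    months = dates.month.to_numpy()
    tmax = out["tmax"].to_numpy(float).copy()
    tmin = out["tmin"].to_numpy(float).copy()
    precip = out["precip"].to_numpy(float).copy()

    if isinstance(deltas, MonthlyDeltaSet):
        d = np.asarray(deltas.temp_delta)[months - 1]
        r = np.asarray(deltas.precip_ratio)[months - 1]
        tmax += d
        tmin += d
        precip *= r
    elif isinstance(deltas, QuantileDeltaSet):
        years = dates.year.to_numpy()
        tmean = 0.5 * (tmax + tmin)
        for (y, m) in sorted(set(zip(years, months))):
            sel = (years == y) & (months == m)
            obs_t = float(tmean[sel].mean())
            obs_p = float(precip[sel].sum())
            d = deltas.temp_delta_at(int(m), obs_t)
            r = deltas.precip_ratio_at(int(m), obs_p)
            tmax[sel] += d
            tmin[sel] += d
            precip[sel] *= r
    else:
        raise TypeError("deltas must be MonthlyDeltaSet or QuantileDeltaSet")

    out["tmax"] = tmax
    out["tmin"] = tmin
    out["precip"] = precip
    return out
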