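"""End-to-end orchestration: generate synthetic cells, classify the
current climate, build per-GCM/RCP scenarios, simulate the daily water
balance, derive drought metrics, shift zones, agreement histograms and
regional/variance/Budyko summaries.

All randomness flows from ``RunConfig.seed``; re-running an identical
config reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate_classify as cc
from . import drought_metrics as dm
from . import summarize as sm
from .config import RunConfig
from .scenario_downscale import MonthlyDeltaSet, apply_deltas
from .synthetic_data import (WeatherGenParams, apply_monthly_normals,
                             gen_cell_grid, gen_daily_weather,
                             gen_gcm_delta_params, gen_soil_profile)
from .vegetation import build_vegetation
from .water_balance import simulate

__all__ = ["run_pipeline", "read_table", "write_table", "STAGES"]

log = logging.getLogger("drylandsim")

STAGES = ("generate", "classify", "simulate", "metrics", "summarize")

#: column -> dtype kind for every results table
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "cells": {"cell_id": "int", "lat": "float", "lon": "float",
              "region": "str", "archetype": "str"},
    "classification": {"cell_id": "int", "condition": "str", "gcm": "str",
                       "rcp": "str", "mat": "float", "map": "float",
                       "pet": "float", "ai": "float", "trewartha": "str",
                       "dryland": "bool", "reasons": "str"},
    "zones": {"cell_id": "int", "gcm": "str", "rcp": "str", "zone": "str"},
    "metrics": {"cell_id": "int", "condition": "str", "gcm": "str",
                "rcp": "str", "ddgp0_mean": "float", "ddgp20_mean": "float",
                "t20_mean": "float"},
    "agreement": {"rcp": "str", "level": "int", "n_cells": "int"},
    "regional_summary": {"region": "str", "zone": "str", "variable": "str",
                         "median": "float", "gcm_min": "float",
                         "gcm_max": "float", "n_gcm": "int"},
    "variance_partition": {"variable": "str", "factor": "str",
                           "percent": "float"},
    "budyko": {"region": "str", "omega": "float", "sse": "float",
               "n_cells": "int"},
}

_KIND_CHECK = {
    "int": pd.api.types.is_integer_dtype,
    "float": pd.api.types.is_float_dtype,
    "str": lambda s: pd.api.types.is_object_dtype(s) or pd.api.types.is_string_dtype(s),
    "bool": pd.api.types.is_bool_dtype,
}


def write_table(df: pd.DataFrame, path, schema: dict[str, str] | None = None) -> None:
    """Write a results table as CSV after schema validation.

    Integer/text columns round-trip bit-exactly; floats are written at
    full (shortest round-trip) precision.
    """
    if schema:
        _validate(df, schema, str(path))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a CSV results table and validate it against ``schema``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        for col, kind in schema.items():
            if col in df.columns and kind == "str":
                df[col] = df[col].astype(str)
        _validate(df, schema, str(path))
    return df


def _validate(df: pd.DataFrame, schema: dict[str, str], context: str) -> None:
    for col, kind in schema.items():
        if col not in df.columns:
            raise ValueError(f"{context}: missing required column {col!r}")
        if len(df) and not _KIND_CHECK[kind](df[col]):
            raise ValueError(f"{context}: column {col!r} is {df[col].dtype}, "
                             f"expected {kind}")


# ---------------------------------------------------------------------------
# per-cell work
# ---------------------------------------------------------------------------


def _weather_params(row: pd.Series, config: RunConfig) -> WeatherGenParams:
    return WeatherGenParams(
        mat_target=row["mat_target"], map_target=row["map_target"],
        temp_seasonal_amplitude=row["temp_seasonal_amplitude"],
        precip_seasonality=row["precip_seasonality"],
        wet_day_prob=row["wet_day_prob"], interannual_cv=row["interannual_cv"],
        years=config.years, seed=int(row["seed"]), latitude=row["lat"])


def _run_condition(weather: pd.DataFrame, row: pd.Series, config: RunConfig):
    """Simulate one (cell, climate condition); returns a record dict."""
    profile = gen_soil_profile(row["sand"], row["clay"], row["soil_depth_cm"])
    normals = apply_monthly_normals(weather)
    veg = build_vegetation(normals, profile)
    params = config.wb_params()
    rh = np.full(12, row["rh_pct"])
    wind = np.full(12, row["wind_ms"])
    cloud = np.full(12, row["cloud_frac"])
    result = simulate(weather, profile, veg, row["lat"], rh, wind, cloud, params)

    keep = result.years >= result.years.min() + config.spin_up
    years_kept = result.daily.loc[keep, "date"].dt.year
    pet_annual = float(result.daily.loc[keep].groupby(years_kept)["pet"].sum().mean())
    aet_annual = float(result.daily.loc[keep]
                       .groupby(years_kept)[["evap", "transp", "interception"]]
                       .sum().sum(axis=1).mean())
    cls = cc.classify_temperate_dryland(
        mat=normals.mat, monthly_mean_temps=normals.monthly_temp,
        map_mm=normals.map, pet_mm=pet_annual, sand_max=profile.sand_max,
        ai_min=config.ai_min, ai_max=config.ai_max, sand_limit=config.sand_limit)
    metrics = dm.compute_drought_metrics(
        result, spin_up=config.spin_up, threshold=config.swp_drought_mpa,
        depth_split=config.depth_split_cm,
        frost_threshold=config.frost_threshold_c)
    return {"classification": cls, "metrics": metrics, "normals": normals,
            "pet_annual": pet_annual, "aet_annual": aet_annual}


def _delta_set(gcm_params, rcp: str, scale: float) -> MonthlyDeltaSet:
    temp = tuple(scale * d for d in gcm_params.temp_delta_by_month)
    ratios = tuple(1.0 + scale * (r - 1.0) for r in gcm_params.precip_ratio_by_month)
    return MonthlyDeltaSet(temp, ratios, gcm_label=gcm_params.gcm_label,
                           rcp_label=rcp)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir=None,
                 stage: str = "summarize") -> dict[str, pd.DataFrame]:
    """Run the pipeline up to ``stage`` and return (and write) all tables.

    Stage order: generate -> classify -> simulate -> metrics ->
    summarize.  "classify" and later require simulation (PET feeds the
    aridity index), so per-cell simulations run for every stage beyond
    "generate".  A GCM scenario whose simulation fails is logged with a
    warning and skipped; the run continues.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    stage_i = STAGES.index(stage)
    outdir = Path(outdir if outdir is not None else config.outdir)
    tables: dict[str, pd.DataFrame] = {}

    cells = gen_cell_grid(config.n_cells, seed=config.seed)
    tables["cells"] = cells
    gcms = gen_gcm_delta_params(config.n_gcms, seed=config.seed + 1,
                                warming_range=config.gcm_warming_range,
                                precip_ratio_range=config.gcm_precip_ratio_range)
    log.info("generated %d cells, %d GCMs", len(cells), len(gcms))

    if stage_i >= 1:
        cls_rows, met_rows, zone_rows, budyko_rows = [], [], [], []
        flags: dict[tuple[str, str], dict[int, bool]] = {}
        for _, row in cells.iterrows():
            weather = gen_daily_weather(_weather_params(row, config))
            current = _run_condition(weather, row, config)
            _append_rows(cls_rows, met_rows, row, "current", "none", "none",
                         current, config, stage_i)
            budyko_rows.append({"cell_id": int(row["cell_id"]),
                                "region": row["region"],
                                "aet": current["aet_annual"],
                                "pet": current["pet_annual"],
                                "p": current["normals"].map})
            for rcp in config.rcps:
                scale = config.rcp_scale.get(rcp, 1.0)
                for g in gcms:
                    condition = f"{g.gcm_label}:{rcp}"
                    try:
                        future_weather = apply_deltas(weather,
                                                      _delta_set(g, rcp, scale))
                        future = _run_condition(future_weather, row, config)
                    except Exception:
                        log.warning("scenario %s failed for cell %s; skipped",
                                    condition, row["cell_id"], exc_info=True)
                        continue
                    _append_rows(cls_rows, met_rows, row, condition,
                                 g.gcm_label, rcp, future, config, stage_i)
                    zone = cc.classify_shift_zone(
                        current["classification"].is_temperate_dryland,
                        future["classification"].is_temperate_dryland)
                    zone_rows.append({"cell_id": int(row["cell_id"]),
                                      "gcm": g.gcm_label, "rcp": rcp,
                                      "zone": zone,
                                      "region": row["region"]})
                    flags.setdefault((g.gcm_label, rcp), {})[int(row["cell_id"])] = \
                        future["classification"].is_temperate_dryland
            log.info("cell %s done", row["cell_id"])
        tables["classification"] = pd.DataFrame(cls_rows)
        tables["zones"] = pd.DataFrame(zone_rows)
        if stage_i >= 3:
            tables["metrics"] = pd.DataFrame(met_rows)

        if stage_i >= 4:
            tables["agreement"] = _agreement_table(flags, cells, config)
            tables["regional_summary"] = _regional_summaries(
                tables["metrics"], tables["zones"])
            tables["variance_partition"] = _partitions(tables["metrics"],
                                                       tables["zones"])
            tables["budyko"] = _budyko_table(pd.DataFrame(budyko_rows))

    for name, df in tables.items():
        write_table(df, outdir / f"{name}.csv", TABLE_SCHEMAS.get(name))
    _write_manifest(config, outdir, tables)
    return tables


def _append_rows(cls_rows, met_rows, row, condition, gcm, rcp, res, config,
                 stage_i) -> None:
    c = res["classification"]
    cls_rows.append({"cell_id": int(row["cell_id"]), "condition": condition,
                     "gcm": gcm, "rcp": rcp, "mat": c.mat, "map": c.map,
                     "pet": c.pet, "ai": c.ai, "trewartha": c.trewartha_group,
                     "dryland": bool(c.is_temperate_dryland),
                     "reasons": ";".join(c.reasons),
                     "region": row["region"]})
    if stage_i >= 3:
        m = res["metrics"]
        met_rows.append({"cell_id": int(row["cell_id"]), "condition": condition,
                         "gcm": gcm, "rcp": rcp, "region": row["region"],
                         **dataclasses.asdict(m)})


def _agreement_table(flags, cells, config) -> pd.DataFrame:
    rows = []
    for rcp in config.rcps:
        gcm_labels = sorted({g for (g, r) in flags if r == rcp})
        if not gcm_labels:
            continue
        mat = np.array([[flags[(g, rcp)].get(int(cid), False)
                         for g in gcm_labels]
                        for cid in cells["cell_id"]])
        hist = cc.gcm_agreement(mat)
        for level, n in enumerate(hist.counts):
            rows.append({"rcp": rcp, "level": level, "n_cells": int(n)})
    return pd.DataFrame(rows, columns=list(TABLE_SCHEMAS["agreement"]))


_METRIC_VARS = ("ddgp0_mean", "ddgp20_mean", "t20_mean")


def changes_table(metrics: pd.DataFrame, zones: pd.DataFrame) -> pd.DataFrame:
    """Future-minus-current change of each metric per (cell, GCM, RCP),
    joined with the per-GCM shift zone."""
    cur = metrics[metrics["condition"] == "current"].set_index("cell_id")
    fut = metrics[metrics["condition"] != "current"].copy()
    for v in _METRIC_VARS:
        fut[f"d_{v}"] = fut[v].to_numpy() - cur.loc[fut["cell_id"], v].to_numpy()
    out = fut.merge(zones, on=["cell_id", "gcm", "rcp", "region"], how="left")
    out["cell"] = out["cell_id"]
    return out


def _regional_summaries(metrics: pd.DataFrame, zones: pd.DataFrame) -> pd.DataFrame:
    changes = changes_table(metrics, zones)
    rows = []
    import warnings as _w
    for (region, zone), _ in changes.groupby(["region", "zone"]):
        for v in _METRIC_VARS:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                s = sm.regional_summary(changes, f"d_{v}", region, zone)
            if s.n_gcm:
                rows.append({"region": region, "zone": zone,
                             "variable": f"d_{v}", "median": s.median,
                             "gcm_min": s.gcm_min, "gcm_max": s.gcm_max,
                             "n_gcm": s.n_gcm})
    return pd.DataFrame(rows, columns=list(TABLE_SCHEMAS["regional_summary"]))


def _partitions(metrics: pd.DataFrame, zones: pd.DataFrame) -> pd.DataFrame:
    changes = changes_table(metrics, zones)
    factors = ["cell", "region", "zone", "gcm", "rcp"]
    rows = []
    import warnings as _w
    for v in _METRIC_VARS:
        sub = changes.dropna(subset=[f"d_{v}"])
        if sub.empty:
            continue
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            parts = sm.variance_partition(sub, f"d_{v}", factors)
        for factor, pct in parts.items():
            rows.append({"variable": f"d_{v}", "factor": factor, "percent": pct})
    return pd.DataFrame(rows, columns=list(TABLE_SCHEMAS["variance_partition"]))


def _budyko_table(budyko: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups = [("all", budyko)]
    groups += [(r, sub) for r, sub in budyko.groupby("region") if len(sub) >= 3]
    for region, sub in groups:
        if len(sub) < 3:
            continue
        fit = sm.fit_omega(sub["aet"], sub["pet"], sub["p"], region=region)
        rows.append({"region": region, "omega": fit.omega, "sse": fit.sse,
                     "n_cells": fit.n_cells})
    return pd.DataFrame(rows, columns=list(TABLE_SCHEMAS["budyko"]))


def _write_manifest(config: RunConfig, outdir: Path, tables) -> None:
    from . import __version__
    manifest = {
        "package_version": __version__,
        "python_version": sys.version.split()[0],
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tables": sorted(tables),
    }
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
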