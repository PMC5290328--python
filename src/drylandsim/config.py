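"""Run configuration: every threshold and process parameter used by the
pipeline lives here, with defaults matching the analysis constants
(SWP drought threshold -3.0 MPa, aridity bounds [0.05, 0.5), 90% sand
screen, 0 degC frost threshold, 20 cm depth split, PET correction 1.2,
31 simulated years with 1 spin-up year).  Round-trips through YAML."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .water_balance import WaterBalanceParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    # experiment design
    n_cells: int = 10
    years: int = 31
    spin_up: int = 1
    seed: int = 0
    n_gcms: int = 2
    rcps: tuple[str, ...] = ("RCP45", "RCP85")
    #: RCP forcing intensity relative to the per-GCM delta draw
    rcp_scale: dict = field(default_factory=lambda: {"RCP45": 0.6, "RCP85": 1.0})
    gcm_warming_range: tuple[float, float] = (3.0, 7.0)
    gcm_precip_ratio_range: tuple[float, float] = (0.8, 1.2)

    # classification thresholds
    ai_min: float = 0.05
    ai_max: float = 0.5
    sand_limit: float = 0.90

    # drought metric thresholds
    swp_drought_mpa: float = -3.0
    frost_threshold_c: float = 0.0
    depth_split_cm: float = 20.0

    # water-balance process parameters (see WaterBalanceParams)
    water_balance: dict = field(
        default_factory=lambda: dataclasses.asdict(WaterBalanceParams()))

    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.years < self.spin_up + 1:
            raise ValueError("years must exceed spin_up")
        if self.n_cells < 1 or self.n_gcms < 1:
            raise ValueError("n_cells and n_gcms must be >= 1")
        if not self.ai_min < self.ai_max:
            raise ValueError("require ai_min < ai_max")

    def wb_params(self) -> WaterBalanceParams:
        return WaterBalanceParams(**self.water_balance)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rcps"] = list(self.rcps)
        d["gcm_warming_range"] = list(self.gcm_warming_range)
        d["gcm_precip_ratio_range"] = list(self.gcm_precip_ratio_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("rcps", "gcm_warming_range", "gcm_precip_ratio_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def demo(cls) -> "RunConfig":
        """Small desk-scale configuration (smoke runs and examples)."""
        return cls(n_cells=20, years=5, n_gcms=2, rcps=("RCP85",))
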