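# drylandsim

Daily, multi-layer, process-based ecosystem water-balance simulation and
climatological analysis of temperate drylands — on fully synthetic,
seeded inputs, so the entire pipeline is testable at desk scale.

The pipeline generates synthetic cells (daily weather, layered soil
profiles, monthly atmospheric climatologies, per-GCM monthly change
signals), classifies cells as temperate drylands (mean annual
temperature > 0 °C, Trewartha group D, UNEP aridity index in
[0.05, 0.5), < 90 % sand), constructs future daily forcing with
hybrid-delta downscaling, simulates the daily water balance per cell and
climate condition, derives ecological-drought metrics (DDGP0/DDGP20
drought durations, deep-transpiration fraction T20/T), and summarizes
results with two-step GCM medians, agreement histograms, unique-variance
partitioning, Budyko-curve ω fits and the symmetric agreement index λ.

## Modules

| module | contents |
| --- | --- |
| `drylandsim.synthetic_data` | seeded weather/soil/grid/GCM-delta generators, monthly normals, global 0.3125° raster geometry |
| `drylandsim.climate_classify` | Trewartha groups, aridity index, temperate-dryland classifier, shift zones, GCM agreement, warm/wet overlap, winter precipitation |
| `drylandsim.vegetation` | shrub/C3/C4 composition, monthly biomass + phenology, root profiles (1 − β^d), soil depth from rooting depth |
| `drylandsim.water_balance` | PET (Penman-family with day-length dependence, ×1.2 correction), snow, interception, cascading-bucket percolation, bare-soil evaporation, stress-limited transpiration, hydraulic redistribution, daily closure < 1e-6 mm |
| `drylandsim.scenario_downscale` | hybrid-delta monthly change signals, mean and 17-bin quantile modes |
| `drylandsim.drought_metrics` | snow/frost eligibility, depth-group SWP, longest-run drought durations, T20/T, year aggregation with spin-up |
| `drylandsim.summarize` | two-step regional summaries, Whittaker-style unique-variance partition, Fuh curve + ω fitting, Duveiller's λ |
| `drylandsim.pipeline` / `drylandsim.cli` | end-to-end orchestration, schema-validated CSV tables, run manifest, `drylandsim` CLI |

## CLI

```bash
drylandsim run-all --seed 1 --outdir results/demo          # demo config
drylandsim generate --outdir results/cells                 # cells only
drylandsim run-all --config myrun.yaml --rcp RCP45 --rcp RCP85
```

Write a template config with Python:

```python
from drylandsim import RunConfig
RunConfig.demo().to_yaml("myrun.yaml")
```

Outputs are delimited text tables (`cells.csv`, `classification.csv`,
`zones.csv`, `metrics.csv`, `agreement.csv`, `regional_summary.csv`,
`variance_partition.csv`, `budyko.csv`) plus `manifest.json` with the
config hash and seeds; identical configs reproduce byte-identical
tables.

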