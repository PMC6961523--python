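# shelfbed

Desk-scale benthic biogeochemistry for muddy and permeable shelf-sea
sediments: a layered bed model (oxic / nitrate-transition / anoxic) with
organic-matter pools, a five-group benthic food web, a ripple-driven
pore-water exchange parameterisation for permeable sands, a first-order POM
mass-balance box model, and a scenario runner with a model–observation
comparison harness — all driven by seeded synthetic pelagic forcing.

## What is in the box

| module | contents |
|---|---|
| `shelfbed.forcing` | seeded daily synthetic forcing (spring/autumn bloom pulses, stratified temperature and oxygen, M2+S2 tidal bed stress with the spring–neap beat) and replicate-observation fixture generation |
| `shelfbed.permeable` | bed stress → log-law velocity → ripple pressure difference → Darcy velocity → advective diffusivity → effective oxic-layer diffusivity |
| `shelfbed.organic_matter` | labile DOM / semi-labile POM / refractory POM / buried pools per element (C, N, P, Si), detritus partitioning, exponential depth profiles, bacterial refractory breakdown, burial |
| `shelfbed.biota` | aerobic + anaerobic bacteria, meiofauna, deposit and suspension feeders; Holling type-II uptake with preference weighting, Q10 scaling, fully mass-closed routing |
| `shelfbed.nutrients` | three-layer nutrient contents with sorption partitioning, oxygen penetration depth (quasi-steady closed form), nitrification, denitrification, silicate dissolution, relaxation exchange with the water column |
| `shelfbed.massbalance` | `dQ/dt = p − l` box model with exact exponential integration, annual budgets, seasonal transfer-function analysis, turnover-rate fitting, burial accumulation timing |
| `shelfbed.scenarios` | builtin configurations `A`, `A1`, `G`, `G0`; the coupled daily simulator with per-step element-conservation ledgers |
| `shelfbed.compare` | scoring of model output against replicate observation CSVs (bias, RMSE, within-range flags) |

The four builtin scenarios: `A` is the muddy reference run (porosity 0.68,
no permeable enhancement); `A1` modifies exactly four parameters (refractory
breakdown rate ×5, detritus split 9:1 → 1:1, deposit-feeder mortality ×4,
suspension-feeder mortality ×2); `G` is the sandy site (porosity 0.44,
permeability 5.0e-11 m²) with the ripple-driven exchange enhancement; `G0`
is `G` with the enhancement switched off.

## Command line

```sh
shelfbed simulate --scenario A1 --years 21 --out out/          # full run
shelfbed forcing --out forcing.csv                             # synthetic forcing
shelfbed permeable --stress stress.csv --out exchange.csv      # exchange chain
shelfbed massbalance --lambda 2 --input 20 --out box.csv       # box model
shelfbed compare --model out/ --obs obs.csv --out scores.csv   # scoring
```

All outputs are CSV with unit-bearing column headers; scenario and forcing
configurations are YAML (unknown keys are rejected with the offending key
named). `simulate` also writes the resolved configuration and a diagnostics
JSON with the maximum ledger residual and the final-two-year periodicity.

## Conventions

Carbon is carried in g C m⁻², nutrients in mmol m⁻²; molar conversion uses
12.011 g C mol⁻¹. Diffusivities are m² s⁻¹ internally and convert to
m² day⁻¹ only at the time-stepping boundary (86 400 s day⁻¹). Depth is
positive downward from the sediment–water interface; the calendar is
365-day years with no leap handling. Physiological and exchange rate
constants other than the published scenario deltas and site constants are
calibration values; `shelfbed.scenarios.provenance()` tags every parameter
as `paper` or `calibration`.
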