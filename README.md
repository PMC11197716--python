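# pasm — peri-urban agricultural sector model

A price-endogenous partial-equilibrium sector model for analyzing
pesticide-use reduction mandates in a peri-urban region. The model
allocates crop acreage across districts to maximize the sum of consumer
and producer surpluses subject to commodity balances, input linkages,
district land endowments, a crop-mix convexity cone around historical
acreage vectors, and district- or region-level pesticide quantity caps.
A scenario grid crosses reduction levels (0–30%), technology regimes
(no mechanized chemical application / rice only / all crops), imposition
scale (district / region), and market closure (price taker `P_fixed` /
closed regional economy `P_free`) into 66 scenarios.

The package also contains:

* a **synthetic data generator** producing complete model input bundles
  (default 9 districts × 15 crops), paired-subsample farm surveys with
  injected technology effects, and tiny instances whose welfare optimum
  is known in closed form (used as solver oracles);
* a **budget engine** turning survey tables into technology-specific
  crop budgets (equivalent-annual-cost machinery annualization,
  paired-subsample summaries, percentage-difference technology effects);
* **reporting metrics**: Laspeyres/Paasche/Fisher indexes, validation
  ratio tables with arithmetic and revenue-weighted means, pesticide
  intensity, district deviations from prescribed targets;
* a small bundled reference dataset (citywide totals, the published rice
  budget summary, and the baseline validation tables).

Price-taker instances are linear programs solved with HiGHS through
`scipy.optimize.linprog`; price-endogenous instances are concave
quadratic programs solved by a built-in Mehrotra predictor-corrector
interior-point method with an active-set KKT polish (no external QP
solver is required). Duals (land rents, pesticide shadow prices) are
recovered from the KKT stationarity conditions.

## Command line

```sh
# write a synthetic bundle directory (CSV tables + survey.csv)
pasm generate --seed 42 --out bundle/

# solve the full 66-scenario grid (or a comma-separated id subset)
pasm run --bundle bundle/ --scenarios all --out results.csv
pasm run --bundle bundle/ --scenarios R3_TechB_region_P_free --out one.csv

# baseline validation table against the bundle's observed data
pasm validate --bundle bundle/ --out validation.csv

# percent changes, price indexes and district target deviations
pasm report --results results.csv --out reports/
```

Scenario ids follow `R{0..5}_{TechB|TechR|TechA}_{district|region}_{P_fixed|P_free}`;
at zero reduction the imposition dimension is vacuous and normalized to
`region`.

## Layout

```
src/pasm/
  domain_data.py        bundle types, loading, validation, results I/O
  synthetic_data.py     generators (bundles, surveys, known equilibria)
  budget_engine.py      EAC annualization, survey summaries, tech budgets
  demand_supply.py      inverse-demand calibration and market closures
  sector_model.py       problem assembly, LP/QP solvers, duals, oracle
  scenario_engine.py    grid enumeration, batch runs, percent changes
  metrics_reporting.py  indexes, validation tables, intensity, deviations
  datasets.py           bundled reference statistics
  cli.py                pasm generate|run|validate|report
```
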