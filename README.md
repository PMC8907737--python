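# vegrisk

Risk classification of dietary contaminants — lead in vegetables being the
reference application — for food-safety surveillance analysts. Given national
monitoring data (per-sample concentrations with non-detects), a region ×
food-category consumption table, regulatory limits and toxicological
reference values, `vegrisk` grades every region × category combination into
ordinal risk levels in a data-driven way.

## The model

For each combination *(i, j)* three dimensionless indexes are computed from
the censoring-substituted concentration summaries:

- **Nemerow integrated pollution index**
  `Pc = sqrt((Pmax² + Pave²)/2)` with single-factor indexes `P = X/S`
  (concentration over the regulatory limit `S`). Combines worst-case and
  average contamination.
- **Hazard index** `HI = EDI95/RfD`, the estimated daily intake at
  95th-percentile contamination relative to the oral reference dose
  (`EDI = FC·X/W`, consumption FC in kg/day, body weight W in kg, intake in
  μg/(kg·day)). `HI < 1` is conventionally acceptable.
- **Margin of exposure** `MOE = BMDL01/EDI50`, the benchmark-dose lower
  bound over the median-contamination intake. Larger is safer.

Non-detects are substituted by the GEMS/FOOD rule: LOD/2 when the
non-detect proportion is below 60%, the full LOD otherwise.

The (Pc, HI, MOE) features are standardized and clustered by normalized
spectral clustering (RBF affinity `exp(−γ‖z_u − z_v‖²)`, symmetric
normalized Laplacian, k bottom eigenvectors, k-means in the embedding). The
kernel width γ and the number of clusters k are selected by maximizing the
Calinski–Harabasz index over a grid (γ ∈ 1..10, k ∈ 3..7 by default), so the
number of risk levels is chosen by the data rather than by the analyst.
Clusters are then ordered into levels 1..k by their mean composite
standardized risk `z(Pc) + z(HI) − z(MOE)`.

## Worked example

A synthetic national-scale scenario (20 regions × 9 categories, 30 samples
per combination, five planted risk tiers):

```python
from vegrisk import LeadRiskModel, ScenarioConfig

model, planted = LeadRiskModel.from_scenario(ScenarioConfig.default(seed=0))
results = model.fit(seed=0)
print(results.summary())
```

```
Dietary contaminant risk classification (spectral clustering)
==============================================================
combinations:   180    features: pc, hi, moe
selected kernel width gamma: 1
selected number of risk levels k: 5
Calinski-Harabasz score at optimum: 2064.8

Risk level proportions
--------------------------------------------------------------
           1:   36  ( 20.00%)
           2:   36  ( 20.00%)
           3:   36  ( 20.00%)
           4:   36  ( 20.00%)
           5:   36  ( 20.00%)
  levels 1-2:   72  ( 40.00%)
  levels 4-5:   72  ( 40.00%)

Combinations at level >= 3: 108
--------------------------------------------------------------
  level 5: bean_sprouts - Jiangxi
  level 5: bulb - Sichuan
  ...
```

The scenario plants 36 combinations in each of five contamination tiers;
the grid search selects k = 5 and the assigned levels recover the planted
tiers exactly (adjusted Rand index 1.0 against the `planted` sidecar for
this seed). On real data the level proportions are of course not uniform —
the clustering adapts to whatever structure the indexes carry.

The same pipeline runs from files:

```sh
vegrisk simulate --seed 0 --out inputs/
vegrisk run --sampling inputs/sampling.csv --consumption inputs/consumption.csv \
            --limits inputs/limits.csv --tox inputs/tox.yaml \
            --params 1:10 --clusters 3:7 --seed 0 --out results/
```

which writes `indices.csv`, `ch_scores.csv`, `risk_levels.csv`,
`high_risk.csv` (with exceedance factors), `summary.json` and a
reproducibility `report.json`.

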