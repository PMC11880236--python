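# degradiag

Rule-based diagnosis of cultivated-land quality degradation for county-scale
soil-survey data, with vegetation-index screening and Shapley-value driver
attribution.

Cultivated-land monitoring programmes in southern China's paddy regions
revisit the same parcels across survey rounds, recording topsoil organic
matter (SOM, g/kg), total nitrogen (TN, g/kg), pH and bulk density (BD,
g/cm³) on a cultivated-land parcel map. `degradiag` turns two such epochs
into a degradation diagnosis per parcel and attributes the observed change
to environmental and management drivers. It is written for land-resource
scientists who need the full chain — grading, typing, area accounting,
attribution — as a reproducible library instead of a GIS point-and-click
workflow.

## The model

**Indicator grading.** Five indicators — SOM, TN, pH, BD, slope — are each
classified into four grades (1 best … 4 worst) against land-use-specific
threshold bands (paddy vs dryland); BD is V-shaped, with an optimal
1.00–1.25 g/cm³ band flanked by too-loose and too-compacted classes.
Boundary values resolve to the better grade. The table ships as editable
YAML.

**Composite grade.** With `n_j` the count of indicators at grade `j`
(`Σ n_j = 5`), the parcel's composite grade is

    1  if n₂+n₃ ≤ 1 and n₄ = 0
    2  if 2 ≤ n₂+n₃ ≤ 3 and n₄ = 0
    3  if 4 ≤ n₂+n₃ ≤ 5 and n₄ = 0, or n₄ = 1
    4  if n₄ ≥ 2

The degradation grade is `Grade(d) = Grade_early − Grade_late`; negative
values mean degradation, mapped to severity by levels dropped
(−1 slight, −2 moderate, ≤ −3 severe).

**Degradation typing.** Per-parcel NIR/RED reflectance gives RVI = NIR/RED,
NDVI = (NIR−RED)/(NIR+RED), DVI = NIR−RED. Each single degradation type is
a screening gate on the index change plus a severity read from its
diagnostic property's grade change: acidification (RVI↓, then pH),
fertility decline (NDVI↓, then SOM), erosion (slope > 5° and DVI↑, then
SOM), physical-structure degradation (DVI↓, then BD). Types are diagnosed
independently and may overlap on a parcel.

**Driver attribution.** Eleven drivers (DEM, aspect, slope, mean annual
precipitation MAP, mean annual temperature MAT, distances to rivers/roads,
population, GDP, straw-return rate SRR, fertilizer rate FAR) are screened
for multicollinearity (VIF < 5), a seeded LightGBM surrogate is fitted to
the degradation score (higher = mitigation), and each driver's contribution
is its Shapley value

    φᵢ(v) = (1/|K|!) Σ_R [ v(S_R^i ∪ {i}) − v(S_R^i) ]

with v(S) the surrogate's expected prediction marginalising features
outside S over a background sample. Both an exact 2^|K| subset evaluation
and an unbiased permutation sampler (with Monte-Carlo standard errors) are
provided; drivers are ranked by mean |φ| with a direction from the
feature–φ correlation.

Because county soil-testing datasets are administrative and not public, the
package includes a seeded synthetic-county generator whose planted
degradation (rates, driver effects, index–property couplings) is exact
ground truth for every stage; all tests run against it.

## Worked example

```python
from degradiag import synthetic, diagnostics, summary

county = synthetic.generate(synthetic.SimulationConfig(n_units=2000, seed=1))
diag = diagnostics.diagnose_all(county.units, county.soil, county.spectral)
table = summary.summarize(diag, county.units)
print(table[["dtype", "total_degraded_pct"]].to_string(index=False))
```

prints

```
             dtype  total_degraded_pct
         composite           11.655306
     acidification           18.549055
 fertility_decline           15.771274
           erosion            3.374033
physical_structure            2.882278
```

i.e. under the default scenario (20% of parcels planted with acidification,
15% fertility decline, 2% erosion, 3% physical degradation, index–property
couplings |r| = 0.8) the diagnosed area shares recover the planted rates to
within ~1.5 percentage points; the composite row is the share whose
five-indicator composite grade worsened. The same run from a shell:

```bash
degradiag simulate --out ds --seed 1
degradiag diagnose --in-dir ds --out out/diagnoses.csv
degradiag summarize --in-dir ds --diagnoses out/diagnoses.csv --out out/summary.csv
degradiag attribute --in-dir ds --dtype acidification --out out/ranking.csv
```

The attribution ranking for acidification puts MAP (direction +1,
mitigating) and FAR (direction −1, exacerbating) in the top two — the
effects planted by the generator.

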