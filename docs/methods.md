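# Methods

## Grading and the composite rule

Each of the five indicators (SOM, TN, pH, BD, slope) has four grade classes
per land use, stored in `degradiag/data/thresholds.yaml` as closed
`[low, high]` intervals, best class first. The published threshold bands
the table mirrors are written without open/closed marks (e.g. "15~20"), so
a single deterministic convention is applied everywhere: classes are
scanned best → worst with closed bounds and the first match wins, which
sends every shared boundary to the better grade. BD uses one ladder for
both land uses (the source table prints a single merged row), and its
classes are interval unions because both compaction and looseness are
penalised. The TN row is implemented exactly as printed even though it
duplicates the SOM row and is implausibly high for total nitrogen in g/kg;
since this cannot be resolved from the source, the table is user-editable
(`load_thresholds(path)`) rather than silently corrected.

The composite rule is purely count-based. Its four branch conditions
partition the full 4⁵ grade-tuple space — the test suite proves this by
exhaustive enumeration rather than assuming it — and worsening any single
indicator can never improve the composite grade (also checked over all
1024 × 5 transitions). Branches are evaluated worst-first (grade 4, then
3, 2, 1) so the rule stays deterministic even if a user edits the
conditions into something overlapping.

Severity caps at *severe* for drops of three or more levels; improvements
and no-change both map to *none*.

## Index screening

"Decreasing tendency" is implemented as a strict comparison of the
two-epoch index delta against a tolerance band: decreasing ⇔ Δ < −ε,
increasing ⇔ Δ > +ε, with default ε = 0 (a two-date change, not a trend
fit — the data structure has exactly two epochs). ε is shared across the
three indices; at ε = 0 a zero delta is neither increasing nor decreasing.
Only per-unit tabular reflectance is accepted; raster-to-parcel zonal
reduction is left to upstream tooling.

`correlation_screen` (Pearson r with the t-based two-sided p) exists to
verify on any dataset that the screening indices actually track their soil
properties; it raises on zero variance rather than returning NaN.

## Type diagnoses

All four single-type rules share one code path: gate, then the same
level-drop severity mapping used by the composite rule, applied to the
type's property-grade pair. Erosion reads severity from the SOM ladder
(the only organic-matter ladder that exists); its gate additionally
requires slope > 5°. Diagnoses are mutually independent — no exclusivity —
so per-type degraded areas may overlap and need not sum to the composite
figure. Units missing any epoch of soil or spectral data are excluded and
counted in `result.attrs["n_incomplete"]`.

## Summaries

Percentages are always taken against total cultivated area, so the four
severity shares of each type close to 100%. Township tables report
degraded area, share of the township's area, and a modal severity over
degraded units with ties broken toward the worse class (conservative for
mapping). Conservation (areas per type summing to the county total, and
township degraded areas summing to the county degraded area) is asserted
to 1e−9 km².

## Driver attribution

The degradation score is the signed grade change (early − late) of the
composite grade or of the type's diagnostic property; higher = mitigation.

*VIF.* VIF_k = 1/(1−R²_k) from an intercept-including OLS of driver k on
the other ten, computed by least squares directly; the cutoff is VIF < 5.

*Surrogate.* A LightGBM regressor (200 trees, learning rate 0.05, 31
leaves, fixed seed, single-threaded) fitted to score ~ drivers; a 25%
holdout reports R² before refitting on all rows. The attribution engine
sees only a `predict` contract, so any regressor can be swapped in.
Zero-variance scores produce a constant surrogate with a `low_signal` flag
and a warning, not an error.

*Value function.* v(S) is the interventional expectation: features outside
S are replaced by rows of a background sample (default 32–100 units,
configurable) and predictions averaged. v(∅) is the background mean
prediction; v(K) the model's prediction of the instance. This convention
is a design choice — the marginalisation for absent features is otherwise
undefined — and is stated rather than hidden.

*Shapley engines.* `shapley_exact` evaluates the weighted-subset form
Σ_S |S|!(|K|−|S|−1)!/|K|! · [v(S∪{i})−v(S)] (guarded at |K| ≤ 15);
`shapley_sampled` averages marginal contributions over uniformly random
orderings, reporting across-permutation standard errors. Within each
ordering the contributions telescope, so efficiency (Σφ = v(K)−v(∅)) holds
exactly for both engines. In the batched instance sampler the same
orderings are shared across instances — unbiased per instance, cheaper per
prediction call. Correctness is cross-checked in tests against brute-force
enumeration of all |K|! orderings and against a closed form for linear
models (φᵢ = βᵢ(xᵢ − mean background)); the four Shapley axioms are
asserted numerically on random value functions.

*Ranking.* Global importance is mean |φ| over an instance sample (all
units by default in the library functions; the pipeline subsamples 128
instances and 32 background rows with the run seed). Direction is the sign
of corr(feature, φ); flat φ columns are flagged `low_signal` with
direction 0.

## Synthetic counties

The generator emulates a two-epoch county soil survey:

* **Units.** Slopes from a plains/hills truncated-normal mixture (70/30 by
  default, hills strictly > 5°), paddy fraction 0.65, lognormal areas
  (median 0.3 km²), townships as spatial grid blocks.
* **Drivers.** Realistic scales (MAP ≈ 1620 ± 65 mm/yr with a spatial
  gradient, MAT ≈ 17.5 °C, exponential river/road distances, lognormal
  POP/GDP with POP→GDP correlation, Beta straw-return rate, FAR ≈ 450 ± 90
  kg/ha) and mild correlations chosen to keep all VIFs well below 5.
* **Soil.** Epoch-1 attributes are land-use-specific truncated normals
  centred inside the second/third grade bands, clipped off grade 4 so
  every unit can degrade 1–3 levels. Per type, the top-rate fraction of
  units by latent propensity (standardized drivers × signed effects +
  N(0, 0.5) noise) is planted as degraded; default rates 20% acidification,
  15% fertility decline, 2% erosion (drawn only from slopes > 5°), 3%
  physical degradation, with severity levels drawn 80/18/2%. Planted units
  jump to a uniform value strictly inside the target grade band; all other
  attributes drift within their epoch-1 band, so unplanted units never
  cross a grade boundary and the planted labels are exact truth. Default
  effect directions: FAR exacerbates acidification and fertility decline,
  MAP mitigates acidification/fertility/erosion, SRR mitigates fertility
  and physical degradation, slope exacerbates erosion and physical
  degradation, river distance exacerbates physical degradation.
* **Reflectance.** Index deltas are coupled to soil deltas by a Gaussian
  copula. Because NDVI = (RVI−1)/(RVI+1), the RVI–pH and NDVI–SOM coupling
  targets are not independent: the generator correlates the pH and SOM
  delta series (shared FAR effect on the planted sets plus within-band
  jitter with correlation 0.6), solves the two-target weight system
  against the empirical delta correlation, and rescales to the feasible
  boundary if the request is jointly infeasible — at the default ±0.8
  targets the realized correlations land within ±0.05. The DVI delta
  loads negatively on the BD delta, with a positive push on eroded units
  so the erosion gate fires; NIR/RED are then solved from the target RVI
  and DVI (RED = DVI/(RVI−1)) with loose clips to (0, 1]. Reflectance
  starts from RVI ≈ 3.2 ± 0.3 and RED ≈ U(0.06, 0.12), i.e. a vegetated
  surface.
* **Seeding.** One integer seed spawns per-stage child generators
  (units/drivers/soil/spectral), so runs are bit-reproducible and stages
  replayable.

What the generator does **not** emulate: spatial autocorrelation of soil
properties, measurement error structure of laboratory assays, seasonal or
sensor effects in reflectance, mixed pixels, or parcels changing land use
between epochs. Passing tests therefore demonstrate the correctness and
internal consistency of the diagnostic chain under its stated assumptions,
not its accuracy on any real county.

## Problem sizes and numerical choices

Reference runs use n = 2000 units (recovery and coupling checks), 800
units × 20 seeds for the driver-recovery experiment (64 instances, 32
background rows, 16 permutations per attribution), and 10 seeds in the
acceptance script. Grade-band sampling keeps a per-indicator margin
(0.05 g/kg for SOM/TN, 0.01 for pH, 0.005 g/cm³ for BD) away from class
boundaries so the boundary tie rule never reclassifies a planted value.
Degenerate inputs are surfaced, not patched: zero-variance soil deltas
warn that couplings are undefined; constant driver columns raise; a
zero-variance degradation score yields a flagged constant surrogate.

## Known limitations

* Severity of a planted unit can be capped when its epoch-1 grade leaves
  fewer levels than the drawn severity; truth labels record the realized
  drop.
* Since eroded units also lose SOM, they can legitimately pass the
  fertility gate (and fertility-planted hill units the erosion gate);
  per-type diagnosed shares therefore run a little above planted rates.
  This mirrors the real overlap of the two processes and stays within the
  ±5-point recovery band at default rates.
* The exact engine is O(2^|K|) value evaluations per instance; at |K| = 11
  it is practical but slower than the sampler, which is the pipeline
  default.
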