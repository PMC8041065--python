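# Methods

This note documents the models implemented in `bsgm_popmap`, the synthetic
data they are exercised on, the parameter choices that matter, and what the
test suite does and does not establish about behaviour on real data.

## 1. Synthetic scenarios

Everything runs on a planar lattice with unit pixel spacing; distances are
Euclidean between pixel centers in pixel units. No projections or geodesy:
the 100 m-style grid of real settlement products enters the models only
through pixel distances, so a planar grid preserves all relevant structure.

A scenario is a pure function of a `ScenarioConfig` (one master seed;
independent sub-streams per operation via fixed offsets), producing:

* **Water mask** — the low tail of a smoothed Gaussian field
  (`water_fraction`, default 0.08).
* **Unit partition** — nearest-seed (Voronoi) regions of `n_units` seed
  pixels drawn on land: contiguous, each with at least one pixel.
* **Static covariates** — elevation (smoothed noise, SD 200 around 500),
  slope (its gradient magnitude), and distance transforms of synthetic
  water/road/protected-area features.
* **Settlement growth** — initial BS clusters (≈2% of land, at least one per
  unit), then per year each candidate pixel (land, non-BS) transitions with
  probability `growth_rate · s / mean(s)`. The suitability `s` is a
  proximity kernel `1 + 4·exp(−DTE/5)` (bounded range, so probabilities
  never clip for growth rates ≤ 0.2) times a per-unit lognormal growth
  propensity with log-SD `growth_heterogeneity` (default 0.75). The
  propensity term matters: with spatially homogeneous growth every unit's
  settlement share grows proportionally, the cross-sectional ordering of
  units never changes, and an annually updated settlement layer would carry
  no information beyond the initial extent — contradicting the premise the
  whole pipeline rests on. Heterogeneous regional urbanization pressure is
  also the realistic regime. Expected fraction of candidates transitioning
  per year equals `growth_rate` by construction (verified by Monte Carlo).
  The series is monotone; the first and last extents are handed to the
  pipeline as the "observed" epochs, interim extents are withheld truth.
* **Lights at night** — `radiance = 2 + 20·(local BS density) + N(0,
  lan_noise_sd)`, truncated at 0, where local density is a Gaussian
  neighbourhood mean with `lan_footprint = 4` pixels: nighttime-lights
  sensors have footprints several times the analysis grid, so the signal is
  informative about settlement but spatially smeared.
* **Coarse annual RS product** — the truth seen through a *persistent*
  classification filter (each pixel undetectable with probability
  `rs_omission = 0.35`, spurious detections with probability
  `rs_commission = 0.01`; both fields drawn once per scenario, since a
  sensor/algorithm misses the same structures every year), then degraded by
  `coarse_factor × coarse_factor` block-majority vote (ties vote 0) and
  nearest-neighbour upsampling. `coarse_factor = 3` emulates a 300 m product
  on a 100 m grid. Without the classification filter the coarse product is a
  near-perfect duplicate of the true year-specific signal, which real annual
  land-cover urban classes are not.
* **Population** — pixel latent log density
  `α + settlement_effect·exp(−DTE_t/settlement_scale) + γ·z + N(0, noise_sd)`
  with `z` standardised elevation; unit-year counts are the summed pixel
  densities over the unit, rounded. `settlement_scale = 6` px puts a
  peri-urban density gradient well beyond the lights footprint, so
  settlement distance carries information that the LAN layer alone does not.
  The noise model for unit counts is a stated assumption, not an inference —
  interpolated census series have error structure no public source
  characterises.

## 2. BSGMi — demand quantification

Per unit, BS population at the two epochs is interpolated with a growth
curve and BS population density (population per BS pixel) with a natural
cubic spline; the implied BS area `A(t) = BSpop(t)/BSdens(t)` yields annual
transition-demand weights `w_t ∝ max(0, A_t − A_{t−1})` (an interpolative
model cannot remove settlement, hence the clamp), uniform fallback if no
increment is positive. The exact functional form combining the two
interpolated series into weights is not published; the implied-area
construction uses both series and satisfies every stated property
(non-negative, normalised, endpoint-consistent). Each unit's observed period
transition count is then apportioned to years by largest remainder — the
integer vector minimising the maximum deviation from the real-valued quotas
(verified against exhaustive search) — so annual counts sum to the period
total exactly.

Two curve variants are kept, selected by config: `logistic` (the validated
form; two points cannot identify three parameters, so a carrying capacity is
required, default 2× the larger endpoint) and `exponential` (the early
production variant, closed-form `r = ln(v1/v0)/(t1−t0)` from two points).
With more than two observations the two-point rule applies piecewise between
consecutive epochs, keeping the curve exact at every observation. On
accelerating growth the exponential variant shifts transition mass later in
the period than the logistic/spline variant (asserted as a directional
test).

## 3. BSGMi — spatial allocation

A `RandomForestClassifier` (default 500 trees, seeded) is trained on the
observed period's transitions: positives are all pixels that transitioned
between the epochs; negatives an equal-size seeded sample of persistently
unsettled land pixels (class balance; the training design is not published,
so this is a declared default). Covariates: t₀ settlement distance-to-edge,
proportion-settled within radii 1/5/10/15, elevation, slope, protected-area
distance. The class-vote fraction is the period transition probability; for
each year it is multiplied by the unit-rescaled LAN annual difference
(min–max within unit; a degenerate unit gets a uniform 0.5 so an
uninformative difference neither zeroes nor saturates the product) and the
unit-year's demand is allocated to the highest-probability remaining
candidates. Ties break by a seeded permutation (reproducible but positionally
unbiased); any shortfall carries to the next year; the final year absorbs all
remaining candidates. Only pixels in the observed t₁∖t₀ transition set are
ever candidates, so endpoint agreement is bitwise and the series monotone.

## 4. Population disaggregation

The per-year density model is a bagged ensemble of CART regression trees
with package-managed bootstrap (so each tree's out-of-bag rows are known
exactly), `min_samples_leaf = 5` (the standard regression-forest node size),
500 trees by default, response = log unit population density. The log
follows standard dasymetric practice and stabilises the fit; since pixel
predictions are renormalised within units, any monotone transform of scale
drops out of the final surface.

**Permutation importance (Per.Inc.MSE).** Per tree, the OOB MSE is compared
with the OOB MSE after permuting one covariate's OOB values; the differences
are averaged across trees and expressed as a percentage of the mean per-tree
baseline OOB MSE. Normalising by the pooled baseline rather than per tree is
deliberate: the per-tree ratio's denominator is correlated with its
numerator, which biases the estimate upward for uninformative covariates,
whereas the pooled form is centred at zero for pure noise (cross-checked
against the canonical R implementation's unscaled importance).

**mtry tuning** scores candidates `⌊p/3⌋·2^k` (k = −2..2, clipped to [1, p])
by OOB MSE with a small forest and keeps the default `⌊p/3⌋` unless a
candidate improves it by at least 5%, mirroring the stepwise logic of the
standard tuning routine.

**Covariate elimination** repeatedly refits and drops all covariates with
Per.Inc.MSE ≤ 0 until none is dropped or `min_retained = 3` remains (the
floor prevents elimination from emptying a degenerate model). A consequence
worth stating: a *single* pure-noise covariate's importance is symmetric
around zero (its OOB values are exchangeable with their permutation), so one
fit eliminates it only about half the time; what the procedure reliably does
is prune most of several noise columns while keeping the true drivers, and
across a scenario's many per-year models the noise column is dropped in the
clear majority.

**Redistribution.** Pixel weights are `exp` of the forest prediction, zeroed
on water; pixel population = unit count × weight / unit weight sum. A
populated unit with all-zero weights falls back to a uniform split (logged).
Unit sums reproduce the counts to < 1e−9 relative; each year is modelled
independently.

## 5. WIR meta-analysis

`WIR = rank / n` with ranks descending in Per.Inc.MSE, average ranks for
ties: most important = 1/n, least important = exactly 1. (The alternative
convention placing the most important covariate at exactly 0 is incompatible
with the ratio definition; the ratio is implemented.) Being rank-based, WIR
is invariant to any strictly monotone transform of the importances.

Tests: Kruskal–Wallis (tie-corrected, df = k−1, chi-square tail) for
year/region differences; Dunn post hoc z-tests on mean rank differences with
tie correction, Holm-adjusted, run unconditionally but flagged for use only
when the omnibus rejects; one-sample Wilcoxon signed-rank for WIR-difference
contrasts against a zero median — exact null by convolution over doubled
midranks for n ≤ 25 (handles ties exactly), normal approximation with
continuity and tie corrections above. Holm adjustment is the usual
step-down with running maximum. Quartiles for boxplot summaries use linear
interpolation (type 7) so summaries are bit-reproducible. Sign convention
for a contrast "first minus second": positive differences mean the first
covariate was *less* important.

The grouping of Dunn tests (per-year vs pooled years within regions) is
exposed as an option rather than fixed, since either is defensible.

## 6. Problem sizes and suite design

Scenario sizes are chosen for desk-scale completeness: interpolation-skill
scoring uses 64×64 grids, 4 units, 13 years, 3 seeds (median interim-year
pixel accuracy ≈ 83%, comfortably above the 80% working threshold; a static
"carry t₀ forward" baseline sits near 79%). The known-mechanism recovery
suite uses 64×64, 40 units, 13 years, 20 replicates in the strong-signal
regime (`settlement_effect = 4`, `noise_sd = 0.02`, `covariate_effect =
0.03`, `growth_rate = 0.08`, `growth_heterogeneity = 1.5`): there the
year-specific settlement covariate's median WIR beats the historical-t₀
covariate's in ≥ 80% of replicates, the structural analogue of the
year-specific-vs-historical contrast on real data. Forest sizes in tests
(100–200 trees) are below the production default of 500; importance ranks
are stable from a few hundred trees, and the tested properties are rank- and
count-based.

## 7. What the synthetic results do and do not show

The generator emulates the *statistical structure* of the real inputs —
monotone settlement growth with regional heterogeneity, a lights proxy with
a coarse footprint, an annually available but systematically flawed RS
settlement product, census counts tied to settlement proximity — not their
content. Passing tests establish that the pipeline recovers known mechanisms
under controlled conditions and that its accounting invariants (mass
conservation, endpoint agreement, integer transition budgets) hold exactly.
They do not establish accuracy on real landscapes: real settlement
morphology, census error structure, sensor intercalibration (e.g. between
lights products), and multi-country border effects are all outside the
generator. Importance conclusions remain conditional on the covariate set —
correlated covariates share rank mass, so a covariate's WIR can shift when
near-duplicates enter or leave the model, which is intrinsic to
permutation importance rather than an artefact of this implementation.
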