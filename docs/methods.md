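# Methods

This note documents the statistical machinery in `recredit`, the design
choices made where the problem left them open, and what the synthetic
experiments do and do not demonstrate about real offset portfolios.

## 1. Common-practice estimation

Inventory data arrive as *conditions*: one record per homogeneous parcel
of a field plot, carrying region strata (supersection, ecosection), a
single forest-type code, per-species fractional basal area, standing-live
aboveground carbon density (tCO₂e/acre), and an acreage **expansion
factor** — the population acreage the condition represents.

Common practice for a stratum is the ratio of expansion-weighted sums,

    CP = Σᵢ dᵢ·aᵢ / Σᵢ aᵢ ,

i.e. total carbon over total acreage — never a plain mean of densities.
Carbon and acreage are summed separately before taking the ratio, which
makes the estimator exactly acreage-additive: the supersection-wide value
is the total-acreage-weighted combination of its assessment-area values
(tested as an identity).

**Variance.** We use the standard delta-method (Taylor linearisation)
ratio-estimator variance treating conditions as independent sampling units
with the expansion factor as the size variable:

    var(CP) = 1/(n·x̄²) · Σᵢ (yᵢ − CP·xᵢ)² / (n−1),   xᵢ = aᵢ, yᵢ = dᵢ·aᵢ.

This matches design-based forest-inventory practice for per-acre
attributes.  Strata with a single condition get variance 0 with a logged
warning: no within-stratum variance is estimable, and silently inventing
one would misstate the Monte Carlo intervals.  We aggregate over site
class and inventory period rather than stratifying by them; the stratum
keys are (supersection, assessment area) for the regulator-style estimate
and (supersection, forest type) for the species-specific alternative.

## 2. Forest-type classification

One classifier per supersection, trained on (species-composition vector,
forest-type code) pairs from the inventory.  Vectors are embedded over the
union of species seen in the supersection; absent species are 0.

* **Decision rule.** Probability of type *t* = share of training vectors
  labelled *t* among all training vectors within Euclidean distance *r* of
  the query.  Euclidean distance is the natural choice on bounded
  compositional vectors; no rescaling is needed.
* **Zero-neighbor fallback.** A query outside every radius ball takes its
  single nearest neighbor's label with probability 1.  Every project must
  receive a classification; fallbacks are counted and logged so heavy
  reliance on them is visible in the audit trail.
* **Radius selection.** Grid search over 21 geometrically spaced radii in
  [0.05, 1.5] (compositions on the simplex are at most √2 apart), scored
  by stratified 5-fold cross-validated weighted F1 of argmax predictions,
  averaged per fold.  Ties break toward the smaller radius (locality).
  Folds are stratified by label when the smallest class permits, plain
  K-fold otherwise (logged); shuffling is seed-controlled.
* **Degenerate cases.** A single-label supersection returns that label
  with probability 1 and score 1.0 (warning logged).  Project species
  unseen in training are dropped and the composition renormalized; a
  composition with no known species is an error, not a silent guess.
* Projects that report species only project-wide have that composition
  applied uniformly to every assessment area they span.

## 3. Credit replication and recomputation

Upfront issuance is reconstructed from the digitized components as

    credits = [(IC + WPₚ) − (B·A + WP_b) + SE] · (1 − cd),  floored at 0,

with IC the initial onsite pools (tCO₂e), WP the wood-product pools for
project/baseline scenarios, B the 100-year baseline average onsite density
(tCO₂e/acre), A acreage, SE ≤ 0 secondary effects, cd ∈ [0,1) the
confidence deduction.  The placement of the deduction (applied to the full
net quantity) is a reconstruction choice isolated in one kernel function
for auditability.

**Rescaled common practice.** Rather than substituting our alternative CP
outright, each project's *reported* CP is multiplied by the
assessment-area-acreage-weighted ratio of the alternative (classifier-
probability-weighted mean of per-forest-type CPs) to our own recomputation
of the assessment-area CP.  Any change in credits is then attributable
purely to the aggregation choice, not to imperfect reproduction of the
original numbers.  A config switch allows hard (argmax-style) pooling via
the classifier output, but the probability-weighted default uses the full
posterior.

**Baseline re-selection.** Projects whose baselines sat exactly at the old
constraint (the overwhelmingly common case) are assumed to sit exactly at
the new one.  The minority that kept a margin above the constraint keep
the same absolute margin above the new one — conservative about developer
behavior.  If the rescaled CP exceeds the project's measured initial
density, recomputed credits are 0: the project is 100% over-credited, and
per-project over-crediting can never exceed issuance (nothing can be
clawed back that was not issued).

Program aggregation sums per-project errors (issued − recomputed;
positive = over-credited), reports the net as a percent of analyzed
credits and in dollars at a configurable price (default $13.67/tCO₂e),
and applies the same transforms per Monte Carlo draw.

## 4. Monte Carlo uncertainty propagation

Forest-type CP estimates carry sampling variances; assuming Gaussian
noise, each of `n_draws` (default 1000) iterations draws every forest-type
mean density once and recomputes the whole chain.  Key choices:

* **Coherence.** The draw perturbs the forest-type means and rebuilds both
  the numerator (alternative CP) and denominator (assessment-area CP,
  reconstructed as the acreage-weighted combination of the same perturbed
  type means) of the scaling ratio from the *same* draw, preserving the
  correlation implied by deriving both from one dataset.  Independent
  perturbation would inflate the intervals; a switch
  (`perturb_assessment_cp=False`) holds the denominator at its point
  estimate instead.
* **Negative draws** are kept inside the propagation (the Gaussian
  assumption applied literally); a negative rescaled CP is floored at 0
  only where credits are computed, with a logged counter.
* **Keyed streams.** Random streams are keyed per (forest type, draw) via
  a CRC of the stratum key mixed with the seed, so adding a project, a
  stratum, or reordering inputs never changes another stratum's draws.
* Program percentiles are computed on per-draw program totals — the median
  of totals, not the total of medians (the two provably differ once any
  project's error distribution is censored at its issuance cap; asserted
  in the tests).

## 5. The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth available in closed form:

* Conditions per supersection: ecosection sampled by area weight (each
  ecosection shifts type means by an additive offset, emulating climatic
  heterogeneity); forest type sampled uniformly over the supersection's
  configured types; species fractions ~ Dirichlet(centroid ×
  concentration); carbon density ~ Normal(type mean + ecosection offset,
  type sd) properly truncated at 0 (truncation, not clipping, so the
  configured mean stays interpretable); expansion acreage ~
  Uniform(1000, 8000) acres, the broad range of per-condition population
  expansions in national inventories.
* Ground truth: because expansion acreage is independent of density, the
  population CP of a forest type is the ecosection-area-weighted
  truncated-normal mean, and an assessment area's CP is the equal-weight
  mean over its member types (types are sampled uniformly).  Recovery of
  these values within 3 SE is a standing test.
* Projects enroll single conditions with probability ∝ exp(γ·z), z the
  standardized carbon density: γ = 0 is uniform enrollment, γ ≈ 5
  approaches gems-only selection.  Only conditions whose density exceeds
  their assessment area's true CP are eligible (only above-average forests
  earn upfront credits).  Species are thresholded at 5% fractional basal
  area and renormalized, mirroring how project paperwork reports
  composition.  A configured fraction of baselines (default 0.89) sits
  exactly at CP; the rest sit above it by folded-Gaussian noise
  (sd 2 tCO₂e/acre).  Acreage ~ Uniform(500, 5000) acres, confidence
  deduction ~ Uniform(0, 0.1), secondary effects ~ Uniform(−2000, 0)
  tCO₂e, wood products 0 by default — plausible magnitudes for a mid-size
  IFM project, not estimates of any real portfolio.  Issuance uses the
  same formula as the replication step, which is why synthetic issuance
  replication is exactly R² = 1.

**Two deliberate study conditions.**  The *density-homogeneous* landscape
gives every forest type in an assessment area the same carbon
distribution (types differ only in species).  There the regional average
is representative of every member type, the eligibility filter cannot
favor any type, and uniform enrollment yields program errors statistically
indistinguishable from zero — isolating the claim that crediting error is
a creature of selection against *unrepresentative* averages, not of the
recrediting machinery.  The *density-stratified* landscape pools 60/120/190
tCO₂e/acre types into one assessment area; there net over-crediting is
positive even at γ = 0 (the eligibility rule itself selects dense types)
and grows monotonically with γ.  Note that over-crediting as a *percent*
of issuance can dilute at extreme γ — the densest parcels also carry the
most initial carbon and earn the most credits — so the monotone-harm
property is stated on net tCO₂e.

## 6. Numerical and testing notes

* Tolerances: ratio-of-sums vs brute-force oracle at 1e-9 relative;
  ground-truth recovery at 3 SE per stratum; percentile ordering exact.
* The Gaussian-quantile calibration check (error linear in one perturbed
  density; empirical p5/p95 vs ±1.645σ within 5% of σ) is run at 20,000
  draws: the empirical 5th-percentile estimator has sampling sd ≈ 6.7% of
  σ at 1,000 draws, larger than the tolerance itself, so the check is made
  seed-robust by raising the draw count (sd ≈ 1.5% of σ) rather than by
  loosening the band.
* Problem sizes used in the test and acceptance runs — 500–600 conditions
  per supersection, 40–200 projects, 200–1,000 draws — keep each stage in
  the seconds range while leaving every standard error small relative to
  the effects being detected.
* Determinism: generation, classifier CV and Monte Carlo are all driven by
  explicit seeds; identical configuration and seeds give byte-identical
  output files.

## 7. What the synthetic results do not show

The generator reproduces the *structure* of the analysis inputs, not the
ecology of any real region: real inventories have spatially correlated
plots, site-class and ownership heterogeneity, measurement error in basal
area, multi-supersection projects, and forest types whose species
signatures overlap far more than the demo landscapes (where classifier
F1 = 1 is by construction; real species-to-type mapping is substantially
noisier).  Successional change in composition (e.g. hardwood-dominated
stands transitioning back to conifer) is not modeled: the classifier sees
species as they stand today.  Passing tests therefore validate the
estimators, the crediting algebra, the selection mechanism and the
uncertainty propagation — they do not by themselves quantify over-crediting
in any actual program, and the dollar figures attached to synthetic
portfolios are illustrative transforms at a fixed price, not market
estimates.  Leakage, permanence and whole-project additionality are
outside scope.
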