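# Methods

This note documents the statistical procedures `pollinet` implements, the
design of its synthetic-data generators, and the numerical choices made
where a textbook definition leaves room. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Niche overlap

Resource overlap between a wild pollinator and the focal species is
computed from their visit-count vectors over the site's plants. Two
variants are provided because "Morisita's index" in the literature covers
both:

* `morisita` (default): the count-corrected original,
  C_λ = 2Σxᵢyᵢ / ((λ_x + λ_y)·X·Y) with λ_x = Σxᵢ(xᵢ−1)/(X(X−1)).
  It corrects for finite sampling but can slightly exceed 1 on small
  samples (e.g. x = y = (2, 2) gives 1.5). It requires both totals ≥ 2;
  for a species with a single collected individual the implementation
  falls back to the proportion form with a logged warning.
* `horn`: the Morisita–Horn proportion form,
  C_H = 2Σpᵢqᵢ / (Σpᵢ² + Σqᵢ²), bounded in [0, 1].

The claim "ranges from 0 to 1" strictly holds only for the proportion
form, which is why both are implemented and every output table records
which variant produced it. Overlap uses raw visit counts per plant — a
pure network-matrix computation, with no normalisation by floral
abundance. Wild species with a single recorded individual are retained.

Site-level responses are community-weighted means, Σwᵢvᵢ/Σwᵢ with
weights = species abundance (column totals of the network). Category-level
CWMs average only the species carrying the label; a label with no species
at a site yields no row, so the site × category table for the trait models
is unbalanced by construction.

## Plant functional diversity

Encoding: corolla length is z-scored over the global species pool (sample
sd); colour and flower type become one 0/1 indicator column per level,
left unscaled. A categorical trait with a single observed level is dropped
with a warning (it contributes no distance). The z-score/raw-dummy choice
is recorded in output metadata so sensitivity runs are comparable.

A Euclidean distance matrix over the pooled species list is ordinated by
principal coordinates analysis: the Gower-centred matrix −½JD²J is
eigendecomposed, axes ordered by decreasing eigenvalue, positive axes
retained. Euclidean input cannot produce negative eigenvalues, but the
implementation guards the case anyway: materially negative eigenvalues
(relative tolerance 1e-8) trigger one square-root distance correction and
a retry. By default m = 3 axes are used downstream — a three-dimensional
trait space, even though dummy expansion creates more columns; the
distance is computed in the full expanded space and the ordination
compresses it. m is configurable.

There is one global PCoA; all sites are scored in that shared space.
FRic of a community is the convex-hull volume of its species in the first
m axes divided by the hull volume of the entire pool, hence in (0, 1]
with 1 attained by the full pool (or a subset with the same hull). FDis
is Σaᵢ‖xᵢ − c‖/Σaᵢ with c the abundance-weighted centroid and aᵢ the
floral relative abundances. A community with fewer than m+1 affinely
independent points has no m-dimensional hull; this aborts the run with
the site named, and the remedy is to reduce m for the whole run — never
per site, because hull volumes at different dimensionality are not
comparable and the standardisation would be meaningless.

The plant community of a site is every species with a floral-abundance
row there (a superset of the visited plants); the global pool is the
union over sites.

## Pollinator trait similarity

Gower's coefficient over four equally weighted traits: proboscis length
and body length (continuous, partial similarity 1 − |a−b|/R with R the
trait's range over the pooled species list), foraging-range class
(binary) and taxonomic family (nominal; one trait, not one dummy per
family, so a family mismatch costs exactly one of four slots). With no
ordinal traits, Podani's extension reduces to Gower's original partial
similarities. Ranges are global, not per site: a given species pair must
score identically wherever it co-occurs. Trait bands relative to the
focal's morphology (proboscis ≈ 5 mm, body ≈ 12 mm) are half-open —
proboscis [0,4), [4,7), [7,∞); body [0,8), [8,15), [15,∞) — closing the
conventional printed gaps (3.9–4.0 mm etc.); the treatment of values in
those gaps is a convention of this implementation. Families with fewer
than ten collected individuals (pooled over all sites) are relabelled
"other" before the family model.

## Multimodel inference

Continuous predictors are centred and scaled by the sample (n−1) standard
deviation so slopes are comparable; scaling metadata is kept for
back-transformation. Responses that can be zero (CWM overlap) are
ln-transformed with an offset of half the smallest positive value,
recorded in output. Focal abundance enters as ln(count); the offset rule
is still applied defensively although a count of zero cannot occur (the
focal is required at every site).

Candidate sets are all sub-models of the global model that respect
marginality (an interaction only together with every lower-order
component), including the intercept-only model. For a global model with
mains A, F, T, Temp and interactions A:F, A:T, F:T, A:F:T this yields 19
hierarchical structures on {A, F, T} × 2 for the free main Temp = 38
candidates; for the category models (A, Temp, Cat, A:Cat) it yields 10.

Fixed-effects models are fitted by OLS; random-intercept models by
maximum likelihood, not REML, because REML log-likelihoods are not
comparable across different fixed-effect structures and the whole point
of the candidate set is exactly that comparison. k counts the intercept,
slopes, the residual variance and (for mixed models) the random-intercept
variance. AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Δ and Akaike weights are
computed over the full candidate set, and the Δ < 6 filter is applied for
presentation only, never renormalised. R² is the ordinary coefficient of
determination for OLS and the variance-partition marginal/conditional
pair for mixed models (the fixed-effects share, and fixed plus random,
of total variance).

Model averaging is full ("zero substitution"): a term absent from a model
contributes estimate 0 and SE 0 to that model's share. The unconditional
standard error is the classic Burnham–Anderson estimator
SE = Σₘ wₘ √(SEₘ² + (βₘ − β̄)²), and the 95% CI is ±1.96·SE (normal
multiplier; at n = 51 the difference from a t quantile is negligible).
Conditional averaging is available behind a flag. Term importance is the
summed weight of the models containing the term.

Numerical details of the mixed fits: the optimiser is retried across
L-BFGS, BFGS, CG and Powell, rejecting non-finite log-likelihoods (a
boundary artefact when the random-intercept variance collapses to zero);
fixed-effect SEs are computed from the fitted variance components as
(Σ_g X_g'V_g⁻¹X_g)⁻¹ with V_g = σ²I + σ_b²11' via Sherman–Morrison, which
stays well-defined at the σ_b² → 0 boundary; residuals for diagnostics
are marginal (fixed part only), for the same reason.

VIF_j = 1/(1 − R²_j) from regressing predictor j on the other mains
(interactions excluded); perfect collinearity reports +∞ with a warning.
Moran's I uses inverse-distance weights with zero diagonal, expectation
−1/(n−1), the normal-approximation variance and a two-sided p. For the
site × category models, residuals are averaged per site before testing.
Site coordinates are planar km — adequate at a ~50 km study extent.

## Synthetic data

Two independent tiers, deliberately not conflated: parameter-recovery
tests need exact known truth on the regression scale, which no
mechanistic simulator can provide, while metric tests need realistic
network structure, which no linear model can provide.

**Regression tier.** Standard-normal predictors, response = Xβ + ε with
Gaussian noise; interactions are products of mains; an optional site ×
category expansion adds additive category effects and a Gaussian site
random intercept. OLS on a zero-noise draw recovers β to machine
precision, which pins the data-generating scale.

**Mechanistic tier.** Emulates a 51-grassland single-visit survey on a
steep elevational gradient: 8–35 flowering plants per site (mean ≈ 20),
~24 pollinator species and ~81 wild individuals per site (16–332), a
honeybee-like focal (proboscis 5 mm, body 12 mm, central-place, Apidae)
present everywhere with log-normal abundance clipped to [2, 768],
temperature 18–38 °C drawn independently of focal abundance and coupled
to elevation (150–2100 m) through a lapse-rate relation with noise.
Trait spans: corolla 0.05–33 mm, proboscis 0.4–16 mm, body 4–22.5 mm.
Each individual pollinator is counted once, so a species' visit total at
a site is centred on its individual count (the survey's visit and
individual totals nearly coincide).

Visits of pollinator p to plant q are Poisson (negative-binomial behind a
flag) with rate proportional to floral abundance × a Gaussian
proboscis–corolla matching kernel exp(−(proboscis − corolla)²/(2σ²)),
σ = 2 mm by default, normalised so the expected total equals the species'
individual count. An optional hard-accessibility rule zeroes plants whose
corolla exceeds proboscis + tolerance; it is off by default because a
structurally inaccessible plant set would give a species an all-zero rate
row, which the simulator treats as an error.

For the community patterns of interest to emerge at all, between-site
variation in community trait composition has to exist — in the emulated
survey it is created by the gradient design. The generator therefore
builds ecological structure that links every similarity trait to resource
choice:

* species carry an elevation optimum rank-correlated (0.5) with their
  (log) morphology, and site membership and abundance follow a Gaussian
  suitability of sd 250 m around that optimum — strong turnover across
  the 1950 m gradient, as on real alpine gradients;
* families have characteristic body sizes (Apidae large, Halictidae
  small, …) and body predicts proboscis through a tight allometry, so
  family composition moves community morphology;
* foraging class is family-determined: bees and wasps are central-place
  nest provisioners, flies and sawflies are not;
* families carry fixed flower-type preferences (hoverflies on open
  discs, long-tongued bees on deep zygomorphic flowers; non-preferred
  types visited at 5% of the rate) — treated as biological constants, not
  per-run draws, so the mechanism does not depend on a structural
  lottery;
* central-place foragers (including the focal) respond more steeply to
  local floral abundance (exponent 2.2 vs 1), reflecting mass recruitment
  to rewarding patches;
* per-site family composition varies (bee- vs fly-dominated assemblages)
  via a Dirichlet around the pool frequencies.

An optional archetype mode draws plant traits from k distinct archetypes,
used to test that more diverse plant communities dilute overlap with the
focal at high focal abundance.

What the mechanistic tier does **not** emulate: colony dynamics, foraging
movement, within-season phenology (the emulated design is one snapshot
per site), intraspecific trait variation, and any guarantee about
regression-scale coefficient values. Passing tests on this tier show that
the metric pipeline recovers the patterns the mechanism builds in — not
that real data contain those patterns. The similarity–overlap Spearman
correlation across 51 sites is a single-realisation statistic with true
ρ around 0.4 under the default design; its p < 0.05 check has roughly
80% power per seed, so an occasional seed fails the significance clause
while still showing a positive correlation.

## Problem sizes and runtime

The default test suite simulates one full 51-site study, one reduced
12-site study, 100 + 100 regression-tier datasets for the
recovery/type-I checks, 100 paired 3-site simulations for the archetype
contrast, and two complete pipeline runs for the byte-reproducibility
check; it completes in a few minutes on one CPU. `scripts/acceptance.py`
repeats the same program at a caller-chosen seed in about a minute. These
sizes were chosen to keep the full validation cycle interactive while
matching the emulated study's dimensions where they matter (51 sites,
n = 51 regressions, 38-model candidate sets).

## Known limitations

* The count-corrected Morisita variant is undefined for totals below 2;
  the fallback to the proportion form is logged but changes the estimand
  for singleton species.
* FRic ignores abundance by definition; rare species move the hull as
  much as dominant ones.
* Full model averaging shrinks weak effects toward zero; averaged
  coefficients are conservative and their CIs are not exact
  confidence intervals for small true effects (the recovery tests encode
  this asymmetry explicitly).
* Moran's I with inverse-distance weights assumes planar coordinates; a
  lon/lat mode should convert to great-circle distances first.
* The mechanistic generator's behavioural constants (preference contrast,
  abundance exponents, turnover scales) are plausible but not estimated
  from data; conclusions about real systems require real data.
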