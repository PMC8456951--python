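# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## The model

Each dated sample is a composition `x ∈ S^D`: D strictly positive
oligotype proportions summing to one (D = 6 for the shipped partition).
All analysis happens in the Aitchison geometry, where perturbation
(closed elementwise product) is the group operation and every metric
quantity reduces to log ratios. The package works "in coordinates": a
sequential binary partition (SBP) of the parts defines an orthonormal
basis; the ilr transform maps compositions isometrically to ℝ^{D−1};
ordinary multivariate statistics run there; results map back with the
inverse ilr. Because the transform is an isometry, distances, norms and
total variance are identical for every valid SBP — the choice of
partition affects only the interpretability of individual coordinates,
never the geometry (this invariance is property-tested).

The regression model is, per season s and sample i,

    y_i = a_s + Σ_v b_{s,v} · z_{iv} + ε_i,   ε_i ~ N(0, Σ_s),

with `y_i = ilr(x_i)` and covariates z = temperature (°C), weekly
averaged incident radiation (MJ m⁻² d⁻¹, mean of the 7 days before
sampling), and nutrient concentrations (μM). Fits are per season because
the composition–environment relationship is visibly nonlinear across the
full year but close to linear within the three strata
(winter–spring Jan 1–Jun 15, summer Jun 16–Sep 15, fall Sep 16–Dec 31;
boundaries are month/day rules, so Feb 29 is winter–spring).

Variable selection is forward stepwise: the candidate minimizing the
partial Wilks' Λ p-value enters while p < α (default α = 0.05, chosen so
that effects at the margin of conventional significance are retained;
configurable). For one added variable the transform
F = ((1−Λ)/Λ)·(ν_E−p+1)/p is exact with df (p, ν_E−p+1). The overall
test of a selected model uses Rao's F approximation (labelled `rao` in
reports). Note the overall Λ itself is identical whether computed
directly as det(E_full)/det(E_intercept) or as the product of the
per-step partial Λ values — determinant ratios telescope — so the two
bookkeeping conventions differ only in the F/p attached to the overall
line, and the per-step records are reported regardless.

A temperature-only model is available as a first-class restricted fit
(no re-selection), for judging how much a single dominant driver
explains.

### Back-transformed parameters

Coefficient rows map through ilr⁻¹ to compositions. The intercept
composition is the expected composition at zero covariates (an
extrapolation, rarely physical); a slope composition is the perturbation
applied per unit increase of its covariate, with the uniform composition
1/D meaning "no effect" and parts above 1/D gaining relative share.

## Zero imputation

Log ratios require strictly positive parts, and the type system enforces
this: a vector containing zeros can be closed to proportions but cannot
become a `Composition`, so imputation must run before any geometry.

Replacement is Bayesian-multiplicative and stratum-local. Within each
season, the prior proportion for part j is the closure of the geometric
mean of the observed proportions of j over the stratum's samples that
detected it (a part never detected in a stratum falls back to a uniform
share, with a warning). For sample i with depth N_i the prior strength
is s_i = √N_i, so the posterior zero replacement p_j·s_i/(N_i+s_i)
shrinks with depth — a zero in a 10 000-read sample is stronger evidence
of absence than a zero in a 30-read sample. Observed parts are rescaled
by one common factor, preserving their ratios exactly (tested to 1e-12);
rows without zeros pass through as plain closure, bit for bit. If a
replacement ever exceeds the smallest observed proportion in its row the
package warns that the prior is over-strong. Both the prior proportions
and the strength are overridable.

Samples with fewer than 15 total reads over the subcomposition are
dropped by default before imputation: below that depth the observed
composition is dominated by stochastic presence/absence. The filter
threshold is configurable and every removal is logged.

## The built-in partition

`mvco_sbp()` encodes the six-part partition for the dominant MVCO
*Synechococcus* oligotypes: (1) O2 against the rest — O2 is the
mid-summer pulse type with by far the largest variation against every
other part; (2) the spring group {O1, O3, O6} against the fall group
{O4, O5}; (3) O4 | O5; (4) {O1, O3} | O6; (5) O1 | O3. Rows are ordered
root-first and validated structurally (every row must split a block
created above it).

`sbp_from_variation` offers data-driven support: hierarchical clustering
(ward or complete linkage, ward default) on √t_kj distances, each merge
node becoming a partition row, r-group assigned to the block holding the
lowest part index for determinism. Different linkages can disagree on
intermediate branches, and curating a final SBP from such dendrograms is
a judgment call — which is exactly why the curated partition ships as a
named built-in and the clustering route is exploratory support.

## Ordination

The biplot decomposes `Z = clr(X ⊖ cen(X))` by SVD. The covariance
scaling (rays V·S/√(n−1), scores U·√(n−1)) is used because it is the
convention under which squared distances between ray endpoints estimate
variation-matrix entries — i.e. the plot reads in log-ratio-variance
units; the equality is exact when Z has rank ≤ 2 and is tested that way.
A form scaling (rays V, scores U·S) is available. SVD sign indeterminacy
is resolved by flipping each component so its largest-magnitude part
loading is positive, making outputs byte-reproducible.

## The synthetic generator

The generator emulates the study design the analysis is built for:
~129 samples over 8 years, monthly with denser summer/fall visits;
incident radiation as a sinusoid peaking near day 172 (5–28 MJ m⁻² d⁻¹)
with daily Gaussian weather noise (sd 6, reflecting synoptic cloud
variability — weekly averaging reduces this to ~2); water temperature as
a sinusoid lagging light by 35 days (1–20 °C, anomaly sd 1.5 °C);
lognormal nutrients with no effect on the composition (true nulls for
the selection machinery). Latent compositions follow the same per-season
linear ilr model the regression fits, with iid Gaussian coordinate noise
(sd 0.3); read counts are multinomial at log-uniform depths between 15
and 20 000, so zeros arise from undersampling exactly where the
imputation model assumes they do.

The default season parameters reproduce the qualitative phenology of the
MVCO series — O1 dominant in winter–spring, a sharp O2 summer pulse,
O4/O5 rising together in fall with a nearly constant ratio, O3
quasi-constant — and effect magnitudes in the range the field data show
(full-model Λ per season of order 0.05–0.3). Effect sizes were fixed
once from a power analysis of this design: within a season, temperature
and light are strongly collinear (r ≈ 0.8–0.9, both being smooth
functions of year day), so slopes were sized to give partial-test
noncentralities ≈ 40–70 after discounting by √(1−r²). They are
illustrative defaults, not estimates fitted to any field data.

What the generator does *not* emulate: PCR/copy-number bias in the
environmental series (the mock-community simulator models copy number
and per-strain recovery bias separately), temporal autocorrelation of
residuals, nutrient–composition effects, overdispersion beyond
multinomial sampling, and taxa outside the six-part subcomposition.
Passing recovery tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness of the
model to real-data violations of them.

"Recovery of the generating variable set" in the end-to-end tests means
recall: every generating variable is selected in every season. Exact set
equality is deliberately not required, because forward selection at
α = 0.05 admits false entries at roughly the α rate by construction;
that behaviour is tested separately as the null-calibration property.

## Numerical choices

- Geometry identities are asserted at 1e-10 absolute; with D ≤ 15 and
  n in the hundreds, double precision leaves orders of magnitude of
  headroom. Imputation ratio preservation is asserted at 1e-12
  (relative); the built-in contrast matrix at 1e-12.
- Wilks' Λ uses `slogdet` for stability. A singular full-model SSCP
  (perfect fit) yields Λ = 0, F = ∞, p = 0 rather than an error; a
  singular *reduced*-model SSCP aborts the step, which ends selection —
  once a model fits perfectly nothing further can be assessed.
- Composition construction tolerates a unit-sum residual of 1e-9 and
  renormalizes nothing silently; closure is the caller's job.
- Variation matrices are symmetrized and clipped at zero to absorb
  last-bit negative variances.
- Forward-selection ties in p-value break by candidate column order;
  clustering merge ties follow scipy's deterministic behaviour, and the
  r-group of each derived partition row is the block containing the
  lowest part index.
- Monte-Carlo suite sizes (1000 replicates for null calibration at
  n = 40, 100 replicates for end-to-end recovery at n = 129, depth
  ≥ 2000) were chosen to give binomial confidence intervals tight
  enough to detect miscalibration while keeping the full suite around
  twenty seconds on one core.

## Known limitations

- The imputation prior is estimated from the same stratum it is applied
  to; very small strata make it noisy (the uniform fall-back and the
  over-strong-prior warning are the guardrails).
- Wilks-based selection assumes iid Gaussian ilr residuals;
  autocorrelated residuals (likely in a time series) make the reported
  p-values optimistic. No autocorrelation correction is implemented.
- `sbp_from_variation` produces *a* valid partition, not a canonical
  one; different linkages may disagree.
- The weekly-light window tolerates missing days (mean over available
  days, warning under 4 of 7); no interpolation is attempted.
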