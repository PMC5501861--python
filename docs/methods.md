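# Methods

## Model

The process model is an occupancy-gated open N-mixture model on a 1-km
grid. Occupancy `O[i,t]` is drawn independently per period from
`Bernoulli(phi[i,t])` — there is no persistence term, so a cell can be
re-occupied after local extinction and its population restarted by
neighbourhood recruitment. Abundance evolves by binomial survival and
Poisson recruitment, and the realized abundance is a Poisson thinning of
the expected count `Ntilde = S + R` (kept exactly in that stochastic form
rather than setting `Nou = Ntilde`). Recruitment is proportional to the
barrier-weighted Moore-neighbourhood mean abundance `NEIGH` with divisor
`|n_i| + 1`; we define `delta = exp(chi) * NEIGH` directly, which is
algebraically `log(delta) = chi + log(NEIGH)` for positive `NEIGH` and
extends continuously to `delta = 0` for an empty neighbourhood.

River barriers: for each pair of adjacent cells the centre-to-centre
segment is intersected with the river polylines; a link is severed when
any part of the intersection lies in the *strict interior* of either
endpoint cell. Testing the destination cell alone (the literal reading of
the rule) can produce asymmetric weights when a river hugs one cell; we
block in both directions so the graph stays symmetric. Geometry exactly on
a cell edge does not block — resolved by the strict-interior test.

Vital-rate links are linear in z-scored covariates with quadratic
altitude/rainfall terms (squares of the z-scores, not re-standardized
squares) and a forest × conversion-distance interaction (product of the
two z-scores). Time-varying covariates are standardized with a single
mean/SD pooled over periods so the per-covariate coefficient shared across
periods stays interpretable; the SD uses the population (n) denominator.
Back-transformation is exact to stored means/SDs.

The nest layer is deterministic: `Nnest = round(psi * Nou)` (rounding
makes the level-4 binomial well-defined; psi is in the hundreds, so
rounding distorts the scale by under 0.25%), and `Onest = 1{Nnest > 0}`.
`psi` is interpreted as `b * q * d` in day-equivalents, with `b*q ~ 1` so
the forest-type values are effectively decay days. The aerial-index
regression `log(gnest) = 4.7297 + 0.9796 log(AI)` uses natural logarithms.
Respondent-level interview detection uses each respondent's own
forest-entry flag; respondents without a recorded flag are masked out of
the likelihood entirely, as are all unsampled survey entries.

## Priors and inference

All 45 coefficients have independent uniform priors (log-scale
coefficients U[−8,8]; occupancy logits U[−6,6]; survival, interview,
count-detection and occurrence-detection logits U[−4,4]; recruitment
intercept U[−6,6]; nest-scaling coefficients U[−10,10] — one source table
labels these "Normal (U[−10,10])"; we read the bracketed range as the
uniform support, consistent with every other row).

Sampling is Metropolis-within-Gibbs:

* scalar adaptive random-walk proposals (target acceptance 0.44, batch
  Robbins–Monro adaptation frozen after burn-in, 10% of proposals with a
  10× step to cross ridges);
* joint adaptive-covariance proposals (Haario-style, 2.38/√d scaling,
  covariance estimated from the second half of burn-in) for the three
  11-coefficient link blocks and the interview pair. Blocks are
  deliberately *not* used for the nest-scaling and count-detection
  parameters: a covariance learned from burn-in drift lets joint proposals
  jump up the `psi`–`xi` likelihood ridge, from which return is blocked by
  the `Y ≤ Nnest` support constraint (an irreversible ratchet in
  practice);
* a slice sampler along the `(gamma0, mu_aerial, mu_ground)` ridge
  direction (random slope from {1, 2, 3}, chosen independently of the
  state so the update remains a valid conditional sampler) — the
  likelihood is nearly flat along `psi * xi ~ const` and sharply curved
  across it, which defeats axis-aligned proposals;
* sequential single-site ±1 proposals for the discrete latents (O flips;
  Nou, S, R steps; an S/R exchange that preserves `Ntilde`), using
  closed-form pmf ratios.

Latent states are initialized from the data (the smallest abundance
consistent with the observed counts under the initial scaling factor,
occupancy on wherever anything was detected, one-step backward propagation
so recruitment rates are positive where recruits are needed); parameters
start from domain-plausible jittered values (moderate nest detection, low
interview detection, scaling near 230 days), the usual practice for this
model family. Initialization retries up to 30 times for a finite starting
density and then aborts with diagnostics.

The default engine is a numba-compiled translation of the sweep
(`engine="numba"`, ~5× faster; sequential scan, so no grid colouring is
needed); the pure-python reference engine remains available and both are
validated against exhaustive enumeration of the latent conditionals on
toy models (total-variation error < 0.01) and a conjugate closed form.
Chains are reproducible per seed; the engines follow different RNG
streams. The reference chain protocol is 3 × 100,000 iterations with
50,000 burn-in; convergence is monitored by the classic Gelman–Rubin
between/within-variance Rhat. Credible intervals use type-7 interpolated
quantiles. Latent-state storage is thinned (default every 50th kept
iteration) to bound memory; parameter draws are stored unthinned.

## Synthetic studies

The generator emulates the *structure* of the island-wide survey, not its
geography: smoothed-noise climate/terrain fields, district-block religious
composition, protected-area blobs (distance transform gives DPA),
scattered industrial-agriculture estates whose cumulative footprint grows
each period (distance transform gives CFA; forest is removed inside and
gently eroded near estates), a meandering river, villages with ten
respondents, 25 nest-occurrence sub-cells per cell, and partial transect
coverage (ground 15%, aerial 10%, targeted 5% of cell-periods by
default). Climate fields are Gram–Schmidt-decorrelated against each other
and the structural covariates so that the pre-fit screen (all pairwise
|Pearson r| < 0.45, as applied to the real data) is satisfiable on small
grids; landscapes are re-drawn up to a retry budget otherwise.

The default truth uses the reference observation-layer coefficients and
level-1 coefficients with the reference signs but moderated rainfall
curvature (a small landscape spans a narrower covariate range); the
resulting population declines by roughly a third per decade — the
declining-population regime of the real system. What passing tests on
these data do **not** show: robustness to real-world covariate error,
non-random survey placement (real nest surveys target known populations),
respondent recall bias, or model misspecification — the synthetic data
are drawn from the fitted model family itself.

## Evaluation and drivers

Posterior-predictive fit compares the posterior mean of `Nnest * xi` at
surveyed cells with the observed counts: Pearson r per period, their
average, and the R² of one pooled predicted-on-observed regression
(per-period R² is also reported). Village labels follow the interview
rules: *presence* if any respondent reported the species that period;
*absence* if strictly more than half of the frequent-entry respondents
had never seen it (a respondent counts as "never" when they reported it
in no period, unless an explicit never-seen matrix is supplied);
otherwise unclassified and excluded. Predicted presence is posterior mean
occupancy > 0.5 (configurable; the source analysis does not state its
rule). Sensitivity and specificity are the usual confusion-table ratios.

Driver scores: HLOSS = FR[t−1] − FR[t] (high = threat); CONFL = raw
FR × CFA (low = threat — raw rather than standardized covariates, because
inside converted estates both z-scores are negative and their product
turns large-positive, inverting the orientation); ANTH is the survival
submodel's rainfall/protected-area component at the fitted coefficients on
standardized covariates (low = threat); FRAG = mean occupied-patch size ×
mean reciprocal nearest-patch distance per region (low = threat), with the
isolation factor omitted and flagged when only one patch is occupied.
Patch distance is the minimum over cell pairs of the Chebyshev
centre-distance minus 1 km (the gap width in cells). Scores are converted
to threat orientation, midrank-percentile-ranked across units (regions, or
region × land use — both variants exist), and binned left-closed: Strong
≥ 75, Moderate [50, 75), Mild [25, 50), Minimal < 25; ties land in the
band of their midrank, so all-equal scores are Moderate. The decadal
decline compounds the annualized geometric factor between the first and
last period midpoints (2000 → 2012 by default) over a 10-year horizon.

## Recovery benchmark and known limitations

The recovery benchmark fits seeded 40 × 40 default-scenario datasets with
reduced chains (3 × 10,000, 5,000 burn-in; five replicates in the shipped
test). The 95% credible intervals cover the generating intercepts in
>90% of cases. Convergence at that reduced length is incomplete for a
substantial share of parameters: the `psi * xi` product is only weakly
identified by binomial dispersion, its traversal is gated by integer
latent reallocation (measured integrated autocorrelation times of a few
thousand iterations), and the 11-coefficient logistic blocks also need
longer chains — the reference protocol's 100,000 iterations exist for a
reason. Chains at the reduced length should be read as approximate
intervals, not converged posteriors; the shipped convergence test
documents this honestly rather than hiding it.

Other limitations: no age/sex structure, density dependence, or occupancy
persistence beyond the model as written; detection constant per protocol;
no real-CRS geometry (grids are abstract kilometre lattices); the
percentile driver classes depend on the chosen comparison units.
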