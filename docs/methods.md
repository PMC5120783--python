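# Methods

## The problem

Momentary mental-state scores from experience-sampling (ESM) studies of
general-population samples are bounded, discrete and heavily
floor-inflated: most people, most of the time, rate negative affect
(NA) and paranoia (PAR) at the scale minimum. When such a sample is cut
into severity subgroups on a (skewed) person-level symptom score, the
subgroups inherit systematically different variances — the healthiest
quartile is compressed against the floor, the most severe quartile
spreads out. Any between-subgroup comparison of association measures
(correlations, regression slopes of one state at time *t* on another at
*t−1*) is then confounded: differential range restriction can
manufacture a severity gradient in "connection strength" where the
underlying dependence is constant.

This package implements the full chain needed to study that confound:
a synthetic multilevel ESM generator with a constant-coupling ("null")
and a severity-graded ("staging") regime; the descriptive analyses that
characterize the distributional pathology; Gaussian-identity and
inverse-Gaussian (IG) log-link mixed models with severity-moderated
cross-lagged effects and interaction likelihood-ratio tests (LRTs); and
Monte-Carlo experiments comparing the two model families.

## Synthetic data generator

Each person carries a standard-normal latent severity `t_p` (correlated
0.3 within twin families). The observed severity score is a scaled,
noisy lognormal transform of `t_p` capped at 5, giving the familiar
right-skewed checklist-total shape (mean ≈ 1.4, skewness ≈ 2.5).

Within each day, the three latent states follow a stationary VAR(1)

    z_t = m_p + B_p (z_{t−1} − m_p) + ε_t,   ε_t ~ N(0, diag σ²),

initialized from the person's stationary distribution; days restart
independently because the lagged analysis never crosses days. The
person-level mean `m_p` carries the severity loadings (positive for
NA/PAR, negative for PA) plus family- and person-level random
intercepts. In the null regime the coupling matrix `B_p` is the same
`B` for everyone (up to small person-level slope noise); in the staging
regime a per-edge gradient is added proportionally to `t_p`.
An optional per-state amplitude factor `exp(scale_k · t_p)`
(`severity_scale`, zero by default) lets the expressed variance, rather
than the mean, carry the severity link.

Latent states are observed through items: each state contributes its
item count (NA 5, PA 4, PAR 1); item values are the state value plus
N(0, 0.6²) item noise, cut at fixed thresholds into 1–7 ratings and
averaged, so NA scores move in steps of 0.2, PA of 0.25, PAR of 1 —
exactly the grid structure of mean item scores. Thresholds and loadings
were calibrated once so that the default 571-person, 5-day × 10-beep
study reproduces the qualitative subgroup pattern of published
general-population ESM data: overall NA floor near two thirds of
measurements and PAR floor near 90%, both floors melting monotonically
across severity quartiles; NA/PAR subgroup variances rising several-fold
from the lowest to the highest quartile; PA near-normal with
homogeneous subgroup variances (max/min ratio below 1.5); positive
skewness for NA, PAR and the severity score.

Missingness is independent Bernoulli per beep (default completion 0.85)
plus a small independent per-state dropout (0.005); nothing in the
analyses assumes a missingness mechanism beyond that. Persons with
fewer than 17 valid assessments (at least one state present) are
dropped, mirroring standard ESM practice; "valid" deliberately counts
partial assessments, since the pairing step later applies per-model
deletion anyway.

What the generator does **not** emulate: clock-time beep spacing,
zygosity structure beyond a shared family intercept, item-level
severity instruments, informative missingness, or day-of-study trends.
Passing tests therefore speak to the statistical mechanism, not to any
specific empirical dataset.

## Mixed models

The response model for a cross-lagged cell (outcome state at *t*,
predictor state at *t−1*) is a GLMM with, by default, a person random
intercept and random slope (unstructured 2×2 covariance) nested in a
family random intercept, and an independent residual at the lowest
level. Two families are implemented behind one interface:

* Gaussian with identity link (the conventional linear mixed model);
* inverse Gaussian with log link — density
  `√(λ/2πy³) · exp(−λ(y−μ)²/(2μ²y))`, mean `μ`, precision `λ = 1/φ`,
  variance `φμ³` — whose support (y > 0) and right skew match
  floor-adjacent symptom scores, and whose log link turns coefficients
  into score ratios `exp(B)`.

Severity enters as a categorical quartile factor, either as covariate
(common slope) or as moderator with nested coding: one slope per
subgroup and no reference group, so the subgroup coefficients and their
Wald 95% CIs are read directly off the fit. The interaction LRT
compares the two by `χ² = 2Δll` on 3 df. Cross-lagged effects are
deliberately unadjusted for autoregression, and no within/between
decomposition is attempted — both choices are design parity with the
analysis tradition this pipeline reproduces, and both are documented
limitations of it.

### Estimation

The marginal likelihood integrates the random effects out with a
Laplace approximation. Because families are independent, the joint
log-likelihood factorizes over family blocks (dimension 3 for a
singleton, 5 for a twin pair with person intercept+slope each plus the
family intercept); all block solves are batched.

The inner step is penalized IRLS: Fisher-scoring weighted least squares
for the fixed effects and random-effect modes jointly, with
step-halving on the penalized log-likelihood; the fixed effects are
thus profiled at the conditional mode (the strategy of the standard
mixed-model software). The Laplace correction takes the
log-determinant of the negative joint Hessian over the random-effect
block at the mode, using the observed per-observation curvature
`λ(2r² − r)/y`, `r = y/μ` (falling back to Fisher curvature in the rare
case the observed one is indefinite at the mode).

The outer optimization runs L-BFGS-B over the log-Cholesky factor of
the person covariance, the log family SD and the log dispersion, with
forward-difference gradients (step 10⁻⁶ — small enough for curvature,
large enough to sit clear of inner-solver noise). Starting values:
fixed effects from the fixed-effects GLM (statsmodels IRLS), the person
intercept SD from the person-level spread of link-scale residuals, the
dispersion from the GLM deviance. Convergence requires the projected
gradient below 10⁻³ (simulation runs relax to 5·10⁻³) with an
iteration cap of 500. Warm-starting the reduced model's variance
parameters from the full model fitted to the *same* data is used
(validated to give equal-or-better optima); warm-starting across
datasets is not, having been found to bias Monte-Carlo results through
premature optimizer termination.

Wald covariance for the fixed effects is the inverse of the Schur
complement of the penalized information (the random-effect uncertainty
propagates into the fixed-effect block). Dispersion is estimated by ML
jointly with everything else; there is no REML, since the LRT requires
ML. An adaptive Gauss–Hermite quadrature routine (15 nodes,
single-random-intercept models only) is retained purely as a
validation oracle; on 10-cluster × 5-observation IG instances at
realistic dispersion (φ ≈ 0.03) the Laplace log-likelihood sits within
0.1 of it, and the Gaussian case is exact.

### Rescaling ladder

IG regression requires a strictly positive outcome and can be
numerically fragile on ESM scales. Each cell is fitted through a fixed
rescue ladder: (1) raw variables, (2) predictor centered at its grand
mean, (3) outcome shifted +0.5 (scale 1.5–7.5), (4) both. The first
step at which *both* nested models converge wins — the LRT is only
valid when both fits share one scale — and the ladder position plus the
rescaling record are carried through to the rendered table as
footnotes. For the Gaussian-identity family these rescalings are exact
reparameterizations (asserted by test); for the IG family the +0.5
shift changes the model, so it is always reported, never silent.

## Descriptives

Subgroup tables pool measurements (not persons) within severity
quartiles. Variance uses n−1; skewness is the adjusted Fisher–Pearson
standardized third moment; floor/ceiling are exact-boundary percentages
with a 10⁻⁹ tolerance for the floating-point representation of mean
item scores. Quartile cutpoints are the 25/50/75 percentiles with
inclusive upper boundaries (ties fall to the lower group), which makes
the grouping invariant to strictly monotone transforms of the severity
score. Correlation tables are measurement-level and pairwise-complete,
Pearson and Spearman (midranks). The equal-variance cutpoint search
scans all ordered triples from a quantile-coarsened candidate grid
(default 60 levels; prefix sums make each triple O(1)) subject to a
minimum subgroup size, minimizing the max/min subgroup variance ratio —
on floor-inflated states it fails at any tolerance near 1.5, which is
the point.

## Artifact demonstrations

The trivariate demo draws (A, B, C) equicorrelated normal (ρ = 0.5),
applies a monotone skewing transform, adds observation noise to B and C
(default half their marginal SD, constant across the scale, as score
noise is), and splits on quartiles of A. A pure monotone transform
alone cannot produce a monotone subgroup-correlation pattern — the two
tail groups are symmetric in latent space, so subgroup r(B, C) comes
out U-shaped — but constant-scale observation noise breaks the
symmetry: the low groups' compressed signal drowns, and r(B, C) rises
strictly with the subgroup variance of A. The multivariate-normal
control shows max−min subgroup r(B, C) below 0.1 at n = 100 000. The
classical direct-selection attenuation formula
`r' = ρk/√(1 − ρ² + ρ²k²)` is verified against truncation Monte-Carlo
within 0.02 over ρ ∈ {0.3, 0.5, 0.7} × k ∈ {0.4, 0.6, 0.8}.

## Simulation study

The method-comparison experiments use a desk-scale design — 100 persons
× 3 days × 6 beeps, completion 0.9, validity threshold 10 — chosen to
keep roughly a dozen lagged pairs per person while making 300-replicate
runs tractable on one CPU; 300 replicates put the Monte-Carlo SE of a
rejection rate near 0.05 at about 0.013. Each replicate generates a
dataset, filters, groups, builds pairs, and fits the moderator and
covariate models under both families with cold starts; non-converged
replicates are excluded from rates and reported separately. Replicate
seeds are `seed·1 000 003 + rep (mod 2³¹−1)`, so a run is fully
determined by (config, seed, replicates).

Under the homoscedastic near-normal null (symmetric thresholds, no
severity loading) both families' interaction LRTs are approximately
calibrated at α = 0.05 (measured 0.070 Gaussian, 0.047 IG at 300
replicates, seed 1; 0.037/0.030 on a larger 120-person variant).
Under the default floor-inflated null both families reject in excess
of the nominal level (measured 0.120 Gaussian, 0.140 IG at seed 1) —
the variance artifact is real for both. The log link removes the
part of the subgroup slope gradient that is mere level scaling, but not
the part created by floor censoring: with scores bounded at 1 and
subgroup floors falling from ~85% to ~40%, the low-severity subgroups'
response is flattened in *every* metric, and the IG variance function
(`φμ³`) estimates those flattened slopes precisely, giving the IG LRT
comparable power for the artifactual gradient. A generator in which
the log-scale slope stays constant across floor-differentiated
subgroups is structurally impossible under threshold discretization of
a constant-slope latent process, because the observed response at the
floor is zero rather than proportional to the level. The package
therefore demonstrates the artifact itself and quantifies each
family's sensitivity to it, rather than certifying the IG model as
immune — consistent with treating its insensitivity as an open
question to be measured.

The staging-power experiment adds a per-edge coupling gradient
(default target edge PA→NA, the most informative one) and reports the
IG pipeline's detection rate; power is non-decreasing in the gradient.

## Numerical and degenerate-input conventions

η is clipped to ±30 before exponentiation; PIRLS allows 12 step
halvings and 80 iterations; skewness is reported as missing below n=3;
a constant variable's correlations are NaN; quartile grouping raises on
tie-degenerate severity; an LRT on fits with mismatched data raises;
p-values below 0.0005 render as "0.000" in tables; interaction
verdicts treat tied adjacent subgroup coefficients as non-decreasing
and non-converged cells as indeterminate.

## Known limitations

* Laplace (not quadrature) likelihoods: LRT statistics inherit the
  approximation; the AGQ oracle bounds the error only for the
  single-intercept case.
* Finite-difference outer gradients cost ~6 evaluations per step;
  full-scale IG fits take seconds, so the 300-replicate studies run on
  the desk-scale design rather than the full 571-person one.
* The generator's threshold mechanism couples floor masses and
  censoring attenuation; regimes where the two should move
  independently would need a different observation model.
* Wald CIs only; no sandwich/robust errors; no multiple-testing
  correction across the nine cells (parity with the reproduced design).
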