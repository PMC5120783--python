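# esmstaging

Cross-lagged mental-state networks under skew: inverse-Gaussian mixed
models, synthetic experience-sampling data, and range-restriction
artifact simulations.

## The problem

Network studies of psychopathology read the regression coefficient of
one momentary mental state on another at the previous beep ("connection
strength") as the impact of symptom on symptom, and differences in
those coefficients across severity subgroups as evidence that more
severe stages have more tightly coupled symptoms ("staging"). But
momentary negative-affect and paranoia scores in general-population
samples are bounded below, discrete, and massively floor-inflated, and
severity subgroups cut from a skewed symptom checklist inherit
systematically different variances. Range restriction then attenuates
association measures differentially across subgroups: connection
strength can appear to grow with severity while the underlying
dependence is constant.

This package is for methodologists and ESM researchers who want to
study — or guard against — that confound. It provides:

* `esmstaging.synthetic_esm` — a multilevel ESM generator (persons in
  twin families, beeps in days, three states on 1–7 mean-item-score
  scales, skewed person-level severity) whose latent VAR(1) coupling is
  constant across severity (null regime) or severity-graded (staging
  regime);
* `esmstaging.descriptives` — subgroup descriptives (mean, variance,
  skewness, floor/ceiling), Pearson/Spearman tables, floor-by-severity
  profiles, and the exhaustive equal-variance cutpoint search;
* `esmstaging.igglmm` — the numerical core: inverse-Gaussian
  distribution utilities, fixed-effects IG regression, and mixed models
  (Gaussian-identity and IG-log) with Laplace-approximated marginal
  likelihood, person intercept+slope and family intercept random
  effects, Wald CIs, likelihood-ratio tests and a
  rescaling-for-convergence ladder;
* `esmstaging.staging_pipeline` — within-day lagged-pair construction
  and the nine cross-lagged models with severity moderation, rendered
  as a subgroup-coefficient table;
* `esmstaging.artifact_sim` — the subgroup-correlation artifact demo,
  the direct-selection attenuation formula, and null/power Monte-Carlo
  comparisons of the two model families.

## The model

For outcome state y at beep t and predictor state x at the previous
beep on the same day, the moderated mixed model is

    g(E[y_ijk]) = β_g(i) + B_g(i) · x_ijk + u0_i + u1_i · x_ijk + v_j

with person i in family j, severity subgroup g(i) ∈ {1..4}, person
random intercept/slope (u0, u1) with unstructured covariance and family
intercept v. The Gaussian family uses the identity link; the
inverse-Gaussian family — density √(λ/2πy³)·exp(−λ(y−μ)²/(2μ²y)),
variance μ³/λ — uses the log link, so exp(B) is a *score ratio*: the
multiplicative change in the expected outcome per unit of the
predictor. Staging is tested per cell by the likelihood-ratio test of
subgroup-specific slopes against a common slope (χ², 3 df).

## Worked example

```
python analysis/01_simulate_study.py
python analysis/02_describe_distributions.py
python analysis/03_staging_reanalysis.py
```

The first script generates the default synthetic study (571 women in
twin families, 10 beeps/day for 5 days, completion 0.85, persons with
fewer than 17 valid assessments dropped) and prints:

```
simulated 571 women, 5 days x 10 beeps, response prob 0.85
kept 571 persons (0 removed by the <17 valid-assessment filter)
24350 completed assessments; per-person median 43 (range 35-49, design maximum 50)
```

The second prints the distributional pathology that motivates the whole
exercise — subgroup variance of negative affect rising an order of
magnitude while its floor melts:

```
NA variance by severity quartile: 0.091 -> 0.240 -> 0.434 -> 0.821
NA floor %  by severity quartile: 86.5 -> 72.4 -> 57.7 -> 40.6
equal-variance cutpoint search (NA): best max/min variance ratio 3.16 ... NOT achievable at tolerance 1.5
```

The third fits all nine cross-lagged models under both families on the
same pair table (21,495 lagged pairs; identical digests, so any verdict
difference is the model's) and prints the rendered
subgroup-coefficient tables. A cell of the inverse-Gaussian NA block
looks like

```
Symptom severity-level 1   0.105 (0.070; 0.139)*
...
Significance of interaction with severity   Chi-sq = 1.570; df = 3; p = 0.666
```

followed by the staging verdict: a cell supports staging when its
subgroup coefficients are non-decreasing and the interaction is
significant at 0.05. On the seed-42 study the Gaussian family flags
0/9 cells and the inverse-Gaussian family 1/9 (the autoregressive
paranoia cell, subgroup coefficients −0.016 → 0.011 → 0.029 → 0.047,
interaction p = 0.049).
Because the generator ran in the null regime — constant latent
coupling — every flagged cell is a variance artifact by construction.

A score-ratio reading of a fitted coefficient:

```python
>>> from esmstaging import score_ratio
>>> score_ratio(0.049).ratio        # 1.05: +5% expected outcome per predictor point
1.0502...
>>> score_ratio(-0.019).ratio       # 0.981: -1.9%
0.98117...
```

There is also a CLI (`esmstaging simulate|describe|fit|staging|
artifact-demo|null-sim`) mirroring these steps for shell use.

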