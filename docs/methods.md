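# Methods

This note documents the models, numerical choices and known limitations of
`devkinetics`. Notation: E is sucrose molarity (mol/L), t is hours since
the midpoint of the 2 h embryo-collection window, y is the normalized
cumulative response in [0, 1].

## Data model and normalization

The experimental unit is a vial of `n_embryos` counted embryos scored for
cumulative pupae (optionally adults) at each observation time. Replicate
vials at one concentration are averaged point-wise into a treatment curve;
when replicate grids differ, the union of times is used and each vial's
cumulative count is carried forward between its own observations —
cumulative counts are step functions, so this introduces no interpolation
assumption. Averaging happens on counts, before normalization; for
equal-size vials the order is immaterial. Viability is the mean over vials
of (final count / embryos seeded). The treatment curve is normalized by
its final mean count, so every fitted curve starts near 0 and ends at
exactly 1 (`y0 = 0`, `y_max = 1`); an all-zero curve raises an explicit
empty-curve error rather than producing NaNs.

## Primary models

All three primary fits estimate exactly two parameters on the normalized
scale.

**Gompertz** `y(t) = exp(−exp(s_dvp·e·(λ−t) + 1))`. `s_dvp` (1/h) is the
maximum slope of the curve, attained where y = 1/e; λ (h) is the lag — the
tangent at the inflection crosses y = 0 at t = λ. Setting y = 1/2 gives
the closed form `t_mid = λ + (1 − ln ln 2)/(e·s_dvp)`, which the test
suite checks against a bisection root to 1e−9 h. A four-parameter version
with free `y0`/`y_max` is provided for completeness but unused by the
pipeline. Fitting is bounded trust-region least squares
(`scipy.optimize.least_squares`, ftol/xtol/gtol 1e−12) with
`s_dvp ≥ 1e−6`, `λ ∈ [0, max t]`; initialization is deterministic — λ₀ is
the last time at which y = 0 (first time if none) and s₀ the maximum
finite-difference slope — so repeated fits are bit-identical and
independent of point order.

**Dose–response** `y(t) = 1/(1 + 10^(−s_dvp·(log₁₀ t − log₁₀ t_mid)))`,
the pharmacological log-dose logistic with time as dose. `s_dvp` is a
dimensionless steepness per decade of time; base-10 logs are used,
matching the magnitude (≈9–21) of published steepness estimates, which a
linear-time slope could not produce. The model is optimized over
`(s_dvp, log₁₀ t_mid)`. Points at t ≤ 0 have no log-time and sit on the
flat pre-lag part of a developmental curve; the fit excludes them (the
count is recorded) while point-wise prediction at t ≤ 0 is a domain error.
Caveat: the fitted steepness scales roughly like synchrony × timing, so
under stress (falling `s_dvp`, rising `t_mid`) it is only weakly monotone
in E and rebounds at high concentrations; it is retained for comparison
but is the least interpretable of the three synchrony parameters.

**Logit linearization** `ln(y/(1−y)) = a·t + b` by OLS; `s_dvp = a`
(1/h), `t_mid = −b/a`. Boundary points (y = 0 or 1) have no finite logit
and are dropped with their count reported; no continuity correction is
applied, since any correction constant would be a tuning parameter.
Diagnostics for this model are computed on the logit scale. Data generated
by a logistic curve transform to an exact line (R² = 1 to machine
precision), which the tests verify.

Goodness of fit is reported as SSE, R² = 1 − SSE/SStot, and
nRMSE = 100·√(SSE/n)/mean(obs) — RMSE as a percentage of the observed
mean. R² for constant observations is undefined and reported as missing
with a warning.

## Secondary models

A primary parameter across the 11-point concentration grid is fitted with
one line (k = 2) and with two free lines plus intersection breakpoint
(k = 4): `x_c = (b₂ − b₁)/(a₁ − a₂)`.

The bilinear fit enumerates every split of the sorted grid into a left and
right block of at least 2 points each (11 points → 8 candidate splits),
fits OLS per block, and keeps candidates whose intersection is consistent
with the partition: `x_left_max ≤ x_c < x_right_min`, closed on the left
because the piecewise model assigns x = x_c to the first segment. The
admissible candidate with minimal piecewise SSE wins; SSE ties break
toward the smaller split index. This exhaustive search is deterministic
and globally optimal at this problem size, unlike a generic nonlinear
solver. When no candidate is admissible the minimum-SSE split is kept with
x_c clamped to its bracket midpoint and the result flagged — downstream
tables surface the flag rather than hiding it.

Model selection uses `AIC = n·ln(SSE/n) + 2k`, without small-sample
correction (AICc would shift all values by a constant ≈ +13 at n = 11,
k = 4 and is not what the reference AIC magnitudes correspond to).
`ΔAIC = AIC_linear − AIC_bilinear > 2` is read as decisive support for the
kinked norm. Limitation: on straight-line truth with noise at the scale of
the reference residuals, the measured false-positive rate of the ΔAIC > 2
rule is ≈29% (500-replicate simulation in the test suite) — SSE-based AIC
at n = 11 is permissive, so a kink claim should always be read together
with the bootstrap CI.

**Residual bootstrap.** Residuals of the piecewise fit (pooled across both
segments — per-segment resampling is a defensible alternative, but pooling
is the simpler default) are resampled with replacement, added to fitted
values, and the full split search re-run per resample; 95% percentile
intervals are reported for x_c, a₁, b₁, a₂, b₂. Resamples that fall back
to the clamped midpoint are included (and counted); only erroring refits
are dropped, with a hard error if more than 20% fail. All resampling
indices are drawn in one call from one seeded generator, so results are
bit-identical for a given seed and independent of iteration order; the
refits are vectorized as batched OLS over all resamples, which an
equivalence test pins to the loop-based enumeration oracle.

Calibration, measured by the test suite: on bilinear truth with Gaussian
noise at the reference residual scale (σ ≈ 0.0014), the nominal-95%
breakpoint CI covers the true x_c in ≈87% of 200 replicates, and the full
synthetic pipeline recovers the generating breakpoint within the CI in
89/100 runs. Percentile intervals for a non-smooth breakpoint functional
at n = 11 undercover mildly; rescaling residuals for leverage would widen
them but departs from the plain residual bootstrap implemented here. Treat
the intervals as slightly anti-conservative.

## Viability statistics

One-way ANOVA with η² = SSB/SST; Tukey HSD adjusted p-values via the
studentized range (scipy); a greedy insert-and-absorb compact letter
display (presentation aid only — the pairwise p-values carry the
inference); Levene's test on absolute deviations from group means
(equivalent to ANOVA on |deviations|, which the tests assert); and
adjusted Fisher–Pearson skewness and excess kurtosis (bias-corrected, the
spreadsheet SKEW/KURT convention) for residual diagnostics. Viability
fractions are analyzed untransformed; α = 0.05 throughout.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: 11
concentrations 0–1.5 M in 0.15 M steps × 5 vials × 50 embryos on an 8 h
grid. Reading the normalized Gompertz curve as the CDF of an individual's
pupariation time gives the inverse-transform sampler
`t(u) = λ + (1 − ln(−ln u))/(e·s_dvp)`, u ~ U(0,1), whose median is
exactly `t_mid`; a KS test against the model CDF at n = 1e5 is part of the
suite. Per vial, survivors are Binomial(n_embryos, viability(E)) and
event times are censored onto the 8 h grid from 0 h to 24 h past the last
event, so every curve attains its plateau.

Default truth (the generator's study conditions): synchrony norm
b₁ = 0.0427 1/h, a₁ = −0.0466, a₂ = −0.0053, x_c = 0.581 M (the published
stress-response point estimates), with b₂ fixed by continuity; timing norm
anchored at t_mid(0) = 121.7 h and t_mid(1.5 M) = 271.5 h with kink at
0.524 M (a₁ = 40, a₂ = 132 h/M); viability declining linearly 0.85 → 0.55
across the grid — a qualitative match to observed survival declines, not a
published estimate. λ(E) is back-computed from the norms via the t_mid
closed form, so the three truth maps are mutually consistent. Per-vial RNG
streams derive from the root seed by (concentration index, vial index), so
any subset of the design is reproducible in isolation.

What the generator does *not* emulate: between-vial random effects (event
times are i.i.d. given E), larval crowding, time-varying mortality, and a
separate eclosion delay. Passing recovery tests therefore show the
estimator chain is correct under the stated stochastic model, not that
real vials lack extra variance components; with vial effects present, the
bootstrap CIs would likely be narrower than the true sampling spread.

**Observation schedules.** Time 0 corresponds to 9 a.m.; thinning to two
observations per day keeps clock offsets {0, 8} h (9 a.m., 5 p.m.) and
once daily keeps {0}. Downsampling only removes observation times —
retained cumulative counts are untouched. In the shipped simulations,
secondary-fit nRMSE is non-decreasing as schedules thin from 3 to 1 per
day, and once-daily observation of fast low-sugar curves leaves too few
interior points to fit, which the pipeline reports as explicit failures.

## Problem sizes and determinism

The test suite uses 200-replicate calibration studies, a 100-seed
end-to-end recovery study, 500-replicate AIC false-positive simulation,
and n = 1000 bootstraps — sizes at which every stochastic assertion is
reproducible in minutes on one core. All randomness flows from explicit
seeds; identical configuration and seeds produce byte-identical CSV/JSON
output (floats at 6 significant digits), and every secondary result embeds
the hash of its input parameter table and the bootstrap seed.

## Known limitations

- The reference parameter tables are printed at 2–3 decimals; refitting
  them reproduces published breakpoints to ≈0.01 M but small coefficients
  (the post-breakpoint slope, ≈−0.006 against values spanning 0.006) only
  to ≈10%, an input-rounding floor no fitter can cross.
- Percentile bootstrap breakpoint CIs undercover mildly at n = 11 (above).
- ΔAIC > 2 alone overstates evidence for a kink at n = 11 (above).
- The dose–response steepness conflates timing and synchrony; prefer the
  Gompertz `s_dvp` when synchrony itself is the question.
- No mixed-effects pooling across vials; curves are averaged before
  fitting, matching the replicate-averaged design.
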