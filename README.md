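# devkinetics

Quantitative modeling of *Drosophila melanogaster* developmental kinetics
under dietary (high-sugar) stress.

Most fly feeding studies report developmental curves descriptively. This
package turns vial-level cumulative pupariation (or eclosion) counts into a
small set of biologically interpretable parameters and models how those
parameters respond to an environmental variable — here, dietary sucrose
concentration. It is written for experimentalists running embryo-to-pupa
feeding assays (replicate vials of counted embryos scored on a fixed
observation schedule) and for anyone re-analyzing such count data.

## The models

**Primary stage.** Each treatment's replicate-averaged cumulative curve is
normalized by its final count, `y = y_obs / y_max ∈ [0, 1]`, and fitted
with three sigmoid models:

- **Gompertz** — `y(t) = exp(−exp(s_dvp·e·(λ−t) + 1))`, with lag λ (h) and
  synchrony `s_dvp` (1/h), the maximum slope of the curve. The mean
  developmental time follows in closed form:
  `t_mid = λ + (1 − ln ln 2)/(e·s_dvp)`.
- **Dose–response** — a logistic in log10 time,
  `y(t) = 1/(1 + 10^(−s_dvp·(log₁₀ t − log₁₀ t_mid)))`, with dimensionless
  steepness per decade.
- **Logit linearization** — `ln(y/(1−y))` regressed on time by OLS;
  `s_dvp` is the slope, `t_mid` the x-intercept.

`t_mid` measures developmental timing (delay under stress); `s_dvp`
measures synchrony — how tightly individual developmental times cluster.

**Secondary stage.** Treating `t_mid(E)` and `s_dvp(E)` as reaction norms
over sucrose molarity E, each is fitted with a straight line and with a
two-segment ("bilinear") model

```
y = a₁·E + b₁  (E ≤ x_c),    y = a₂·E + b₂  (E > x_c),
x_c = (b₂ − b₁)/(a₁ − a₂)
```

whose breakpoint `x_c` estimates the concentration at which the stress
response changes regime — the operational high-sugar-diet threshold. Models
are compared with the SSE-based Akaike criterion `AIC = n·ln(SSE/n) + 2k`,
and breakpoint uncertainty is quantified by a residual bootstrap
(percentile CIs). A synthetic-data generator (inverse-CDF sampling from the
Gompertz curve, binomial viability, grid-censored observation) provides
ground-truthed experiments for validation, and a sampling-frequency tool
quantifies how fewer observations per day degrade the fits.

## Worked example

Fit the bilinear reaction norm to the packaged per-concentration Gompertz
synchrony estimates (11 sucrose concentrations, 0–1.5 M):

```python
from devkinetics import compare_linear_bilinear, residual_bootstrap_bilinear
from devkinetics.pipeline import load_fixture_table

table = load_fixture_table("s_dvp")
row = table[table.model == "gompertz"].sort_values("concentration_M")
x, y = row.concentration_M.to_numpy(), row.s_dvp.to_numpy()

lin, bil, delta = compare_linear_bilinear(x, y)
ci = residual_bootstrap_bilinear(x, y, n_boot=1000, seed=1)["x_c"]
```

prints (via the obvious f-strings):

```
breakpoint x_c      : 0.5927 M
pre-break slope  a1 : -0.0447 1/(h*M)
post-break slope a2 : -0.0057 1/(h*M)
intercept        b1 : 0.0428 1/h
R^2 (bilinear)      : 0.9889
delta AIC (lin-bil) : 27.29
95% CI for x_c      : [0.501, 0.678] M
```

Read: synchrony declines steeply with sucrose up to ≈0.59 M, then nearly
plateaus; the kinked model is decisively preferred over a single line
(ΔAIC ≫ 2); the bootstrap places the stress threshold between ≈0.50 and
0.68 M. Above this threshold a diet behaves as a high-sugar diet for
developmental kinetics.

The same stages run from the shell:

```
devkinetics simulate --seed 1 -o out/           # synthetic experiment
devkinetics fit-primary out/counts.csv -o out/params.csv
devkinetics fit-secondary out/params.csv --seed 1 -o out/secondary.json
devkinetics frequency out/counts.csv -o out/freq.csv
devkinetics reproduce-tables                    # packaged reference tables
devkinetics viability out/counts.csv -o out/stats.json
```

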