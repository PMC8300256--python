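# Methods

## Model and procedure

The pipeline treats a TNR program's yearly sterilization surgeries as an
index of the free-roaming cat population `N_t` (census counts, where they
exist, are carried alongside and used for the population-based criterion,
the carrying-capacity rescaling, and the observed neutering fractions).
Per-capita growth rates are `r_t = ln(N_{t+1}/N_t)`. Under the Ricker map

    N_{t+1} = N_t · exp(r_m (1 − N_t/K)),

these rates fall exactly on the line `r = r_m (1 − N/K)`, so an ordinary
least-squares fit of `r_t` against `N_t` estimates `r_m` (y-intercept)
and `K` (x-intercept, reported only when the slope is negative — a
non-negative slope has no capacity crossing and the report says so
instead of inventing one). The Malthusian multiplier is `R_m = e^{r_m}`,
carried unrounded everywhere: the campus-program threshold only comes out
at 41% when `e^{0.16} = 1.1735` is used; the two-decimal display value
1.17 would give 40%.

Critical rates follow `s = (R_m − 1)/(R_m − p)` and `s_a = s (1 − p)` with
annual survival `p = 1 − 1/lifespan`. `s` is clamped into [0, 1] (the raw
formula is negative for `R_m < 1`, where no sterilization is needed), and
both are undefined for `R_m ≤ p`, which the code treats as an analysis
precondition failure rather than a numeric answer.

The index-scale capacity is converted to cats by
`K_actual = K_index × census_final / surgeries_final`, using the last year
that has a census; a zero-surgery final year cannot be rescaled and is
reported as such.

### Conventions

* **Rate-year labelling.** `r_t` is indexed by the *earlier* year of its
  pair (the worked example in the replicated tables labels
  `ln(N_1994/N_1993)` as the 1993 rate). The alternative labelling is one
  config switch away (`rate_year_convention`), and the regression of
  rates on counts always pairs each rate with the count it started from,
  so parameter estimates do not depend on the label.
* **Zeros and gaps.** A log-ratio touching a zero or missing count is
  emitted as an absent value with a note, never ±inf. Year gaps are
  flagged on the series, never silently filled.
* **Display rounding** is half-away-from-zero (matching the replicated
  tables); all statistics are carried at full precision internally.

## Statistical engine

All trends are plain OLS with the two-sided slope t-test at df = n − 2
and α = 0.05 — deliberately so: replicating this style of assessment
means replicating its use of unadjusted linear regression on time-series
data (no autocorrelation correction, no heteroscedasticity adjustment).
Outlier screening uses internally studentized residuals with threshold
2.0 and a *single* exclusion-plus-refit round; if exclusion would leave
fewer than 3 points the original fit is kept with a warning. LOWESS
(bandwidth 2/3, 3 robustifying iterations — standard Cleveland settings)
is attached to the growth-vs-surgeries fit as a nonlinearity diagnostic.
Pregnancy proportions are regressed directly on a continuous month index
(the analysis being replicated is linear regression of proportions, not
logistic regression; yearly pooling is available as an option).

Degenerate inputs: a fully constant program (identical counts, all rates
zero) yields a slope-0, p = 1 fit by construction instead of an error;
numerically-zero slopes are snapped to 0 so float dust cannot
manufacture an x-intercept; a constant predictor with varying response
is reported as not-assessable.

## Simulation and regimes

Simulations iterate the map with real-valued state for 20 years by
default (rounding only at display). Regime labels use the standard
Ricker bifurcation thresholds: monotone approach for `0 < r_m ≤ 1`,
damped oscillation for `1 < r_m < 2`, stable cycles for
`2 ≤ r_m < 2.6924`, chaos beyond; negative `r_m` is monotone decline.
Note one divergence from the narrative that often accompanies these
simulations: with `r_m = ln 2.45 ≈ 0.90`, a population starting far above
K collapses, rebounds and then converges monotonically — the
deterministic map does not "collapse again". The simulator reproduces
the map faithfully rather than the prose.

## Synthetic data

Two generators, both driven by NumPy's PCG64 (`default_rng`) from a
single per-run seed, with per-year substreams
(`default_rng([seed, year])`) so output is independent of draw order.

**Ricker-governed** (`generate_ricker_program`): latent exact trajectory;
surgeries = `round(fraction · N_t)`; census = `round(N_t · ε_t)` with
`ε` lognormal(0, `obs_noise_sd`). With no noise and fraction 1 the series
is the rounded exact trajectory, and parameter recovery through the
pipeline is limited only by integer rounding (~1e−3 at K = 400); the
1e−6/1e−8 exact-recovery oracles therefore run on the unrounded
trajectory. The noisy-recovery check uses `r_m = 0.5, K = 400, N_1 = 40`
over 30 years at 5% census noise — a growth phase plus an equilibrium
stretch, chosen once as a realistic colony-scale setting — and measures
recovery on the census channel, where the noise lives (median absolute
`r_m` error across 200 seeds stays below 0.1).

**Managed decline** (`generate_managed_program`): emulates the structure
of long-term programs with documented reductions. The census follows the
straight line from `N_start` to `N_end` with Poisson jitter (the
declines being emulated are described as linear; Poisson keeps counts
integral and is an assumption, not an observed variance). Surgeries are
binomial at the target neutering fraction of each year's population.
Each surgery yields a per-cat record: month uniform, sex Bernoulli(0.5),
pregnancy Bernoulli with a monthly probability declining linearly from
0.35 to 0.03 over the program, adoption with probability 0.3 and
lognormal age (median 4.8 months, σ = 0.6 on the log scale — only the
median is documented for the programs being emulated; returned adults
get a broad lognormal around 36 months), removals = adoptions.
Immigration defaults to 0; the nonzero option simply shifts the expected
census and is an extrapolation knob.

Presets: `orcat_like` (455 → 206 cats over 22 years, fraction 0.22) and
`ucf_like` (68 → 10 over 28 years, fraction 0.16).

What the managed generator does *not* emulate: age structure, spatial
colony structure, seasonality of breeding, survivorship differences
between neutered and intact cats, and real immigration/abandonment
dynamics. Passing tests on it therefore show that the pipeline behaves
as specified on data with the right first-order statistical shape — not
that any conclusion transfers to a particular real program.

## Test design for stochastic properties

Seed-indexed assertions are distributional, not per-seed: with Poisson
endpoints the realized overall reduction has ~1% per-seed probability of
leaving the [0.45, 0.65] band, so an all-seeds assertion would be flaky
by construction. Tests assert the median and a large-majority fraction
instead (e.g. the model-mismatch conjunction — census down ≥ 45%,
growth-over-time not significant, observed median fraction above `s_a`
— must hold in ≥ 75% of 100 seeds; empirically it holds in ~91%).
Problem sizes (100–200 seeds, 20–30 year series) keep the whole suite
around five seconds while leaving the statistics comfortably clear of
their thresholds.

## Known limitations

* The replicated published tables are internally inconsistent for
  several years (printed growth rates vs their own surgery counts); the
  fixtures store both columns verbatim and the replication command flags
  the mismatching years rather than reconciling them. Published
  regression p-values that depend on non-distributable raw data are not
  reproduction targets; the synthetic presets reproduce their
  qualitative pattern only.
* Annual surgeries are a poor abundance index whenever surgical capacity,
  funding or volunteer effort — not cat abundance — drives the count;
  the pipeline reproduces the index-based method, it does not defend it.
* No stochastic Ricker variant, immigration term or contest-competition
  (Beverton–Holt) alternative is implemented; those belong to a
  different model family than the one assessed here.
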