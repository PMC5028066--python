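# Methods

## Model and assumptions

All intervals treat the original and (planned) replication study as
independent random samples from one normal-theory population: normal data
for means, bivariate-normal pairs for correlations, two homoscedastic
normal cells for d-values. Only sampling error is modelled. Real
replications also differ through measurement changes, population drift,
publication bias, and heterogeneity of true effects — a prediction
interval narrower than observed replication scatter can therefore flag
either non-chance deviation *or* a violated assumption, and nothing here
distinguishes the two.

A prediction interval (PI) for a statistic is constructed so that, under
the model, a fraction `level` of replication statistics falls inside it.
Computationally each PI is the confidence interval for the difference
between two estimates of the same parameter — one observed, one an
imagined replication of the planned size — re-centred on the original
estimate.

### Means

`mean_pi` uses `M1 ± t_{N1−1,(1+level)/2} · sqrt(SD1²/N1 + SD1²/N2)`. The
replication variance is unknown before the replication exists, so SD1
serves for both studies; consequently the critical value uses df = N1 − 1,
not the pooled N1 + N2 − 2. At N1 = N2 = N the half-width reduces exactly
to `t_{N−1}·SD·sqrt(2/N)`, the classical equal-n result, which the test
suite checks to 1e-12.

### Correlations

Component intervals come from the Fisher transform, `tanh(atanh(r) ±
z·(n−3)^{−1/2})`, and are combined with Zou's modified asymptotic method:
with the original CI (l1, u1) and the replication-size CI (l2, u2), both
around r1,

    LL = r1 − sqrt((r1−l1)² + (u2−r1)²)
    UL = r1 + sqrt((r1−l2)² + (u1−r1)²)

The quadrature pairs the *inner* arm of one interval with the *outer* arm
of the other, which is what preserves the asymmetry of the sampling
distribution of non-zero r. Two alternative constructions are provided for
comparison: a symmetric simple-asymptotic interval on the r scale (known to
deteriorate as |r| grows) and the simple-asymptotic interval applied on the
z scale and mapped back through tanh.

### d-values

d is the pooled-SD standardized difference; its sampling distribution is a
scaled noncentral t with df = n1 + n2 − 2 and scale `sqrt(1/n1 + 1/n2)`.
Component CIs invert that distribution in its noncentrality parameter: the
upper bound is the ncp whose distribution puts the observed t at its
(1−level)/2 quantile, the lower bound symmetric. The same Zou quadrature
then applies on the d scale. `d_unbiased` implements the Hedges
approximation `d·(1 − 3/(4·df − 1))` with the pooled df.

## Numerical choices

- Noncentrality inversion uses bracketed root-finding (Brent) on
  `nct.cdf(t; df, ncp) − p`, bracket `t ∓ (10·max(1,|t|) + 10)`, absolute
  tolerance 1e-8. The CDF is strictly decreasing in ncp, so the root is
  unique. scipy's `nct.cdf` underflows to NaN deep in the tails; NaN is
  resolved to 0 when ncp > t and 1 when ncp < t before differencing.
  The simulation engine uses the same bracket with vectorized bisection
  (≤200 halvings, tolerance 1e-8) over whole trial arrays.
- Correlation/d PI bounds are **not clamped** to the parameter range.
  Extreme configurations (|r| near 1 with tiny samples) can push a bound
  past ±1; it is reported as computed, with a warning, because truncation
  would silently alter capture behaviour.
- Degenerate inputs (SD ≤ 0, |r| ≥ 1, n below the minimum for the
  transform) raise `ValueError` rather than returning zero-width
  intervals; the downstream transforms are undefined there.
- The confidence level is continuous in (0, 1), applied via the
  (1+level)/2 quantile everywhere; 0.95 is only a default.
- Reports print 2 decimals (round-half-to-even via standard float
  formatting); the library returns full precision and `--precision`
  exposes more digits.
- Zou combination validates that the point lies inside both component
  intervals and that the components share a level; violations indicate a
  caller bug and raise immediately.

## Capture simulation

The capture engine measures interval calibration empirically. Per trial it
draws an original sample, builds the PI (for the planned replication size)
and the original study's CI, draws the replication, and records closed-
interval capture of the replication statistic (boundary ties count as
captured — a measure-zero choice documented for reproducibility).

Generator conditions mirror the validation experiments the method was
published with: means drawn from Normal(100, 15) with N = 50 → 100 for the
headline run (capture is location/scale invariant, so other mean scenarios
default to unit scale); correlations from bivariate normals with unit
marginals via the Cholesky construction (ρx + √(1−ρ²)e), headline ρ = .50
with N = 100 → 200; d-values from two unit-variance cells δ = 0.8 apart,
50 per cell in both studies. The `use_unbiased` flag applies the Hedges
correction to the original *and* the replication d, each at its own df,
before any interval is formed — the only symmetric reading of a
bias-corrected capture experiment.

Sampling is vectorized over trials and chunked at ~2·10⁶ scalars per chunk
to bound memory; a scenario's root seed is split into per-chunk child
streams with `numpy.random.SeedSequence.spawn`, and the chunk size is a
fixed function of the scenario, so a `Scenario` maps bit-for-bit to one
`CaptureResult`.

Default problem sizes: 10,000 trials per scenario, which resolves a
capture percentage to a binomial standard error of ~0.2 points at p ≈ .95
(~0.4 at p ≈ .84) — enough to separate the PI's ~95% from the CI's
~83–84% by a wide margin. Full 50,000-trial runs, matching the scale of
the published tables, are available per row via `Scenario(trials=50000)`
or `predint simulate --trials-override 50000`; the test suite re-runs one
equal-n mean row at that scale. Stochastic assertions in the tests use
three binomial standard errors at the reference rate as tolerance.

## Known limitations

- Everything is normal-theory: non-normal populations, heteroscedastic
  cells, dependent samples, and selection/publication effects are out of
  scope, so passing capture tests demonstrate calibration under the model,
  not robustness to real-data pathologies.
- The Fisher approximation is weak below roughly N = 100 for correlations;
  capture there can drift a few tenths of a point from nominal and is
  reported but not asserted.
- Biased d with very large original cells and very small replication cells
  captures slightly under nominal; the Hedges-corrected arm restores
  calibration.
- Only means, r, and d are supported — no odds ratios, R², η², and no
  meta-analytic pooling across more than one replication.
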