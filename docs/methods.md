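# Methods

## Model

platesim implements the classical plate model of chromatography: the column
is a chain of *n* identical equilibrium stages, and the outlet concentration
of a solute with distribution coefficient *K* and injected concentration
*C0* is the Poisson-shaped band

    C(v) = C0/(1+K) · e^(−v) · v^n / n!

in the reduced-volume coordinate *v = V / (K·vs + vm)*, where *V* is the
mobile-phase volume consumed and *vs*, *vm* are the per-plate stationary and
mobile volumes. The model assumes instantaneous equilibration on each
plate, a linear isotherm (K independent of concentration), no longitudinal
diffusion, and an ideally sharp injection. Band broadening therefore comes
only from the plate statistics; kinetic (rate-theory / van Deemter) effects
are deliberately out of scope.

Time enters through four standard column descriptors: V = F·t, Vm = F·tm,
Vm = n·vm and β = vm/vs. Substituting these collapses the per-plate volumes
and gives

    v(t) = t·n / ((1 + K/β)·tm),

a linear map from time to reduced volume. The per-plate volumes survive
only as derived accessors on `ColumnSpec`; they never enter the simulation.

Maximising C over t (dC/dt = 0) gives the retention-time equation

    tR = tm·(1 + K/β) = tm·(1 + k),   k = K/β,

which the package exposes in closed form (`analytic_retention_time`) and
certifies numerically (`derivative_zero_check`, below) rather than by
symbolic manipulation.

### Numerical evaluation

Both band shapes — the exact Poisson form and the Stirling form
C0/(1+K)·(2πn)^(−1/2)·(v/n)^n·e^(n−v) — are evaluated in log space
(`scipy.special.gammaln` supplies ln n!) and exponentiated at the end.
A literal implementation overflows near n ≈ 170 (double-precision n!);
the log-space route is exact to rounding and is verified to stay finite at
n = 10^5. v = 0 is mapped to C = 0 explicitly to avoid log(0).

The Stirling form is the classroom-friendly variant; its relative error
versus the exact band is the Stirling error of n!, about 1/(12n) uniformly
in v (≈ 0.08 % at n = 100), shrinking monotonically with n. It is intended
for n > 10; the function emits a warning — not an error — below that, since
nothing prevents evaluating it there and the inaccuracy may itself be
instructive.

*v* is treated as a continuous non-negative real even though its origin is
a count of plate volumes; the band is a smooth curve, and the gamma
function interpolates the factorial consistently.

### Gaussian limit

The Poisson band has mean n and variance n in v. Pushed through the linear
map t = v·(1+K/β)·tm/n this gives a Gaussian in time with mean tR and
standard deviation tR/√n, scaled so its time integral equals the
plate-model band area (see below). This parameterisation is the package's
own derivation; the model itself only asserts that the limit exists. The
peak-height-normalised sup-distance between the Gaussian and the exact band
decays like the Poisson skewness, ~1/√n (measured: 0.041 at n = 100,
0.012 at n = 1000, 0.004 at n = 10^4).

### Band area

Because ∫ e^(−v) v^n / n! dv = 1, the change of variable gives the closed
form

    ∫ C dt = C0/(1+K) · (1+K/β) · tm / n  (mg·min/L).

The test suite first verifies this closed form against adaptive quadrature
of the exact band, then uses it as the oracle for the trapezoidal
`profile_area`.

## Peak reading and the derivative certificate

Peak times are read from a simulated trace by discrete argmax followed by
parabolic interpolation through the three samples around the maximum. The
refinement is exact on a sampled parabola and, on these smooth bands,
recovers the analytic retention time to ~1e-5 min on a 0.01-min grid — far
inside the documented one-grid-spacing tolerance. A maximum on the grid
boundary raises an error advising a wider grid rather than returning a
truncated peak.

`derivative_zero_check` evaluates the central difference of C(t) at the
closed-form tR with step h = 1e-5·tR and normalises by (peak height / tR)
to make the residual dimensionless. At the true maximum the residual is
O(h²·tR³·C'''/C) ≈ 1e-8 for the worked cases; the certificate threshold of
1e-6 is comfortably met by every preset solute under both band models.

## Regression

`fit_retention_vs_K` is unweighted ordinary least squares written directly
from the normal equations (centred sums of squares), with Pearson r from
the same sums. This is intentional: the fit is a two-parameter line on a
handful of points and writing it out keeps the package free of a
statistics-dependency for one formula, while a brute-force grid-refinement
least-squares search serves as an independent oracle in the tests. The
degenerate design (< 2 distinct K) raises; a flat response (all tR equal)
returns r = 0, since a trendless exact fit carries no correlation.

## Configuration and presets

Cases are described by a small JSON/YAML schema (`CaseConfig`): column as
{n_plates, dead_time_min *or* dead_volume_mL, phase_ratio}, flow, solutes
each with exactly one of K or the two phase solubilities, an optional
uniform time grid, and the band model (default `stirling`). Validation
errors name the offending field. Derived quantities (tm = Vm/F, K =
stationary/mobile solubility ratio) are logged at INFO so users see the
intermediate numbers.

Three presets encode the worked cases: `case1` (single solute, K = 3 from
0.6/0.2 g/L solubilities, n = 100, Vm = 3 mL at 1 mL/min, β = 2), `case2`
(adds K = 1.8), `case3` (K = 1, 3, 5, 7, 9). The default grid spans
[0, 1.5 × slowest tR] with 2000 points. `run_case` writes the chromatogram
CSV, a peak table, and — when at least three distinct K values are present —
the tR-vs-K regression JSON; with fewer it logs a notice and skips the fit
rather than erroring.

The `Chromatogram` container keeps both the per-solute traces (the overlaid
classroom view, which the CSV export and plots use) and their pointwise sum
(the physical single-detector view). Peaks are located per-solute trace; no
deconvolution of the summed trace is attempted, and no resolution statistic
is computed for partially overlapping peaks — case2's separation question is
answered by reporting the two peak times and their difference.

## Tunable parameters

| parameter | units | default / preset value | role |
| --- | --- | --- | --- |
| n_plates | — | 100 (presets) | column efficiency; peak width ∝ tR/√n |
| dead_time_min (tm) | min | 3 (from Vm = 3 mL, F = 1 mL/min) | unretained elution time |
| phase_ratio (β) | — | 2 | mobile/stationary volume ratio |
| flow_mL_per_min (F) | mL/min | 1 | links volumes to times |
| K | — | case-specific | partition coefficient; sets tR |
| C0 | mg/L | 1 | injected concentration; pure scale factor |
| model | — | `stirling` | band-shape evaluation route |
| grid | min | [0, 1.5·max tR] × 2000 | simulation window/resolution |

## Determinism

There is no randomness anywhere in the artifact: simulations, peak reads
and fits are pure functions of the configuration, and rerunning a case
produces byte-identical outputs. The acceptance script accepts a `--seed`
flag for interface uniformity only.

## Limitations

- Linear, non-interacting solutes: traces superpose exactly; competition
  for the stationary phase, overload and tailing are not modelled.
- No detector noise, baseline drift or injection-width convolution, so
  peak-finding tests exercise geometry, not robustness to noise; on real
  noisy data the parabolic refinement would need smoothing first.
- Isocratic, isothermal runs only — no gradient elution or temperature
  programming.
- Plate-count estimation from peak width (n = 16(tR/W)²-style) is not
  provided.
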