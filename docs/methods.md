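# Methods

## The adaptation model

Per-cycle series (PP displacement in cm, or the head–pelvis correlation
coefficient) are fitted with the three-parameter exponential

    y_n = A + B · exp(−C · (n − 1)),   n = 1, 2, …, N cycles

by nonlinear least squares. The model is evaluated with the **first cycle
at t = 0**, so the intercept is exactly `I = A + B`; this is the
convention under which the reported identities (`I = A + B`,
`AI = (A − I)/(A + I)`) hold without an off-by-one between the intercept
and the fitted curve.

Derived quantities:

- **time constant** `τ = 1/|C|` in cycles; in seconds,
  `τ_s = τ / f` with `f` the platform frequency (cycle duration 5.6 s at
  0.18 Hz, 1.8 s at 0.56 Hz). Time constants are reported positive for
  both rising and decaying fits; the *direction* of adaptation is carried
  entirely by the sign of `AI` (equivalently of `B`). A signed-rate
  convention (`τ = −1/C`) would produce negative values for decaying
  series, contradicting the requirement that a time constant measure an
  elapsed time, so the absolute-value form is used.
- **adaptation index** `AI = (A − I)/(A + I)`, bounded in (−1, 1) for
  positive series, zero when no adaptation occurred, ≈ −0.3 when the
  asymptote is half the intercept.

### Fitting procedure and numerical choices

- Solver: `scipy.optimize.least_squares` (trust-region reflective) with
  analytic Jacobian, parameter/function/gradient tolerances 1e-9,
  iteration cap 10⁴ per start.
- Multi-start: 8 starts, `C₀ ∈ {1, 1/2, 1/4, 1/8}` crossed with both
  signs of `B₀`, where `A₀` = mean of the last 5 cycles and
  `B₀ = y₁ − A₀`. Multi-start guards against the local-minimum fragility
  of single-start conjugate-gradient fits on noisy series. The lowest-RSS
  solution wins; the loop exits early on an exact (zero-residual) fit.
- Bounds: `τ` constrained to [0.2, 3N] cycles. Below 0.2 cycles the decay
  completes between two data points; above 3N the curve is
  indistinguishable from a line at data resolution.
- **Degeneracy flag**: set when `|B| < 0.02·|A|` (flat at data
  resolution) or when the rate sits at a bound. Degenerate fits are
  *retained* in all downstream tables — for weakly adapting series the
  variance of τ̂ grows sharply and consumers should treat those values
  with care, but excluding them would bias condition summaries.
- Goodness of fit: Pearson `R` between observed and fitted values, with a
  two-tailed p from the t distribution on N − 2 df. **This p is
  descriptive, not a calibrated test**: the curve is fitted to the same
  data it is correlated with, so under a pure-noise null the nominal 5%
  level is exceeded (≈16% in simulation at N = 27). It is reported
  because it is the field's customary fit diagnostic; no decision rule in
  the package consumes it, and all fits are kept regardless of it.
- Noiseless identifiability: for any `A > 0, B ≠ 0, C ∈ [0.05, 3]` and
  ≥ 10 cycles, the fit recovers all three parameters to 1e-6 relative
  error (property-tested).

## Cycle segmentation

- Onset: baseline mean/SD over the first 1 s of the platform trace;
  onset is the first sample deviating by more than `k·max(SD, ε)` (k = 5,
  ε = 1e-4 cm guarding noiseless traces), backtracked to the last
  baseline-level sample. Accurate to ±2 samples on protocol-default
  trials.
- Boundaries: positive-going crossings of the post-onset midline (the
  post-onset mean of the platform trace — robust to baseline offset),
  with a hysteresis band of 5% of platform PP; midline crossings are
  phase-unambiguous for a sinusoid. The onset seeds the first boundary.
- Windows deviating from one platform period by more than
  max(1.5 samples, 5% of a period) are rejected (noise-induced crossing
  jitter shifts boundaries by a few samples); trailing partial cycles are
  discarded, never extrapolated.
- PP is computed on raw, unfiltered traces within each window; mean AP
  positions are referenced to cycle 1 (cycle 1 ≡ 0), making them
  invariant to constant offsets.
- Analyses truncate to the first 27 cycles at both frequencies
  (configurable), so LF and HF series are compared over equal cycle
  counts.

## Coordination

The per-cycle coordination measure is the lag-0 normalized
cross-covariance of the within-cycle head and pelvis traces after
mean-centering — i.e. their Pearson r. Centering is required for the
coefficient to be bounded in [−1, 1] and to carry the intended sign
interpretation (positive = same direction). No detrending beyond
centering is applied: a cycle window is short relative to positional
drift. Cycles with a zero-variance trace yield an undefined (NaN)
coefficient and are flagged, not dropped silently.

Group- and trial-level CC averaging is done on Fisher-z transformed
values (`z = atanh(cc)`, with |cc| clipped at 1 − 1e-12) and
back-transformed. The CC course across cycles is fitted with the same
exponential model as the PP series; the CC–PP association is an OLS line
with R² and the slope's two-tailed p.

## Statistics

Spearman rank correlation (PP vs AP position across cycles; rank-based
because the initial cycles are outlying relative to the steady state),
one-sample t (AI vs zero, per condition) and paired t (steady-state vs
initial AP position) are delegated to scipy behind a thin result-type
layer; significance is two-tailed at α = 0.05. Each of these has a
well-posed null and simulation-verified 3.5–6.5% type-I error at
α = 0.05. Repeated-measures ANOVA, sphericity corrections and post-hoc
machinery are intentionally out of scope: the emitted tables are tidy
long-format so any statistics package can run them.

## Synthetic data generator

The generator emulates the protocol's study conditions: sinusoidal
platform translation of 10 cm PP at 0.18 Hz (LF, 27 cycles) or 0.56 Hz
(HF, 31 cycles), 140 Hz sampling, a 5 s quiet-stance pre-period, 20
subjects × 2 trials per condition with lognormal per-subject jitter
(10% SD) on envelope parameters.

Body traces are built as

    x(t) = M(t) + ½·G(n(t))·[√λ·sin(2πf·t) + √(1−λ)·w(t)] + ε(t)

- **Envelope** `G(n) = A + (I − A)·e^(−(n−1)/τ)`, piecewise-constant per
  cycle (the simplest model consistent with a per-cycle PP analysis),
  parameterized by (A, I, τ) — the quantities the analysis reports —
  rather than (A, B, C). With zero noise and λ = 1 the measured per-cycle
  PP equals G(n) exactly up to sampling discretization
  (≤ 2·amplitude·(1 − cos(π·f/f_s)); property-tested).
- **Coordination** is shared/independent variance mixing: both segments
  carry the common fundamental with weight √λ and an independent
  component `w` with weight √(1−λ). `w` is a segment-specific harmonic
  of the platform frequency (head 2f, pelvis 3f) with a fresh random
  phase each cycle. Harmonics are exactly orthogonal to the fundamental
  and to each other over a full period and have the same variance as a
  unit sinusoid, so the within-cycle correlation of head and pelvis
  equals λ exactly in the noiseless limit (shared:independent variance
  λ:(1−λ); 9:1 ⇒ CC = 0.9), while keeping the traces smooth and
  oscillatory. A white-noise carrier would satisfy the same expectation
  but inflate per-cycle max − min by its ~3σ peak factor and distort the
  PP envelope whenever λ < 1; the harmonic carrier keeps that inflation
  modest and multiplicative. λ may follow its own exponential course
  (A_cc, I_cc, τ_cc) to emulate a coordination that consolidates over
  cycles.
- **Mean position** `M(t)` defaults to zero drift (mean positions vary
  little across cycles in this paradigm); an optional linear drift
  supports testing the AP-position operations.
- **Noise** `ε` is white Gaussian on position, default SD 5% of the
  segment's asymptote, emulating within-trial variability of unspecified
  origin.

Default condition envelopes place steady-state amplitudes near the
platform amplitude, with LF time constants at the values reported for
young adults (head EO 1.84 cycles; pelvis EO 1.47, EO-TP 3.16, EO-TG
3.02, EC 3.47), positive AI at LF (≈ +0.08…+0.15), decaying head
amplitude at HF (AI −0.08, eyes closed −0.16) and near-zero pelvis
adaptation at HF — the qualitative pattern the analysis is meant to
resolve.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes (exponential
PP envelopes, controllable coordination, protocol timing), not the
physics that produces it: no inverted-pendulum dynamics, no sensory or
muscular model, no medio-lateral or vertical motion, and a stationary
noise process where real sway variability is structured. Passing
recovery tests therefore validates the *measurement pipeline* — that the
implemented estimators recover known generating parameters under
realistic noise — not any claim about human data.

### Known estimator behaviour under trace noise

Per-cycle PP is an extreme-value statistic: additive trace noise of SD σ
inflates max − min by roughly 2·c·σ (c ≈ 3 for ~780 samples/cycle), so
amplitude estimates (A, I) carry a positive offset under the default
noise, AI is mildly attenuated toward zero, and τ is nearly unbiased
(the offset is approximately common to all cycles). Recovery tests for
amplitudes are therefore run at the series level (noise added to the
per-cycle values, as in the Monte-Carlo acceptance checks) or with
noiseless traces; τ-ordering comparisons across conditions are robust to
the offset. Mixture components with λ < 1 likewise add oscillatory power
and inflate measured PP multiplicatively.

## Problem sizes

Monte-Carlo recovery checks use 500 replicates of 27-cycle series (the
protocol's cycle count); coordination calibration uses 100 seeds;
type-I-error simulations use 1000 replicates. The full demonstration
pipeline processes the protocol-sized cohort (320 trials) in well under a
minute on a laptop-class CPU.
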