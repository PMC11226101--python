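# Methods

## Model and simulation

The simulator integrates the one-variable leaky integrate-and-fire (LIF)
membrane equation with explicit forward Euler on a fixed grid,

    V_{k+1} = V_k + (Δt/ξ)·(−(V_k − V_rest) + R·I_ext),

firing when `V > θ` strictly (equality does not fire) and resetting to
`V_reset`. Defaults are the standard benchmark constants (−65, −65,
−55 mV, 1 MΩ, 12 nA), Δt = 1 ms, 1000 steps, so each trial covers exactly
1000 ms and the drive `R·I_ext = 12 mV` puts the asymptote at −53 mV,
2 mV above threshold. With a fixed time constant the spike period is the
deterministic crossing time of the discrete recurrence; in continuous time
this is `ξ·ln 6 ≈ 1.7918·ξ` under the defaults (used as the integration
oracle: the Euler period converges to it as Δt → 0).

Stochasticity enters through the time constant: after every spike ξ is
redrawn by inverse-transform sampling from a shifted exponential
(`μ − s·log U`) or a Pareto law (`μ·U^(−1/σ)`), with uniforms drawn from
`(0, 1]` so logs and reciprocal powers are always finite. Two simulation
modes exist because the stochastic model admits two readings:

* **ode** — ξ is redrawn inside the membrane equation; each inter-spike
  interval is the deterministic grid-crossing time of its drawn ξ
  (≈ ξ·ln 6), so the interval law is the ξ law rescaled. Mechanistically
  faithful; used in tests.
* **direct** (default for experiments) — the intervals `d_i` *are* the ξ
  draws, accumulated into spike times until the 1000 ms window is
  exhausted. This matches the printed interval distributions exactly and
  is the mode behind the reference experiments.

Since every interval is ≥ μ, at most `T/μ` intervals fit in a window of
length T; the direct mode therefore makes a single vectorised draw per
trial.

### Synapse gate

The synaptic current decays exponentially, `I_s(t) = I_s(0)·e^(−t/τ_s)`,
and a reset is accepted only when `I_s` has fallen below
`ω = I_s(0)·e^(−1)` — equivalently, at least τ_s after the previous spike.
τ_s is not constrained by the reference experiments (the synapse "decays
immediately" relative to the membrane); it defaults to 2 ms, configurable.
Because intervals are ≥ 20 ms, the gate never changes a spike time at the
defaults; a test pins this no-op property at τ_s ≤ Δt. Only the ratio
`I_s/ω` matters, so `I_s(0)` defaults to 1 (arbitrary units).

### σ convention for the exponential law

The exponential sampler is stated as `(−1/σ)·log U + μ` with σ called a
rate yet given in ms (σ = 5 ms). Read literally the excess scale is
1/σ = 0.2 ms; read as an e-folding time it is σ = 5 ms. Both give a
shifted exponential, so every EVT statement holds either way; the sampler
implements the literal formula by default and exposes
`convention="scale"`. The built-in exponential experiment (`fig3`) pins
`convention="scale"`: with a 0.2 ms excess the whole maxima distribution
would span under two 1 ms histogram bins, which cannot produce the
reported well-resolved histogram, while the 5 ms reading reproduces it
directly.

### First interval and silent neurons

The first interval is measured from t = 0 (`d_1 = T_1`); this is
legitimate because `V_init = V_reset` makes the first firing cycle
statistically identical to later ones, and it is toggleable in
`extract_intervals`. Configurations whose asymptote does not exceed
threshold return an empty train with a `SilentNeuronWarning` rather than
raising, so parameter sweeps survive; an experiment aborts only if more
than half its trials are silent.

## Extreme-value pipeline

Per-trial maxima are binned into right-open bins of fixed width (1 ms by
default, matching Δt) starting at `⌊min⌋`, with masses normalised to sum
to one (checked to 1e−12). The limit-law CDFs/PDFs (Gumbel, Fréchet,
reversed Weibull, each with location/scale and, where applicable, shape α)
are implemented from their closed forms and cross-checked against
scipy.stats in the tests; Weibull is included to complete the trinity but
is not exercised by the experiments.

Fitting offers two routes, both populating the same record:

* **histogram_ls** (default, mirroring a fit to the plotted histogram):
  nonlinear least squares matching bin mass to `pdf(center)·bin_width`
  via `scipy.optimize.curve_fit`. Gumbel starts from moment matching
  (scale₀ = std·√6/π, loc₀ = mean − 0.5772·scale₀); Fréchet fits three
  parameters (shape, location, scale) with location initialised at 0 (the
  norming constant b_n of the Pareto domain) and (shape₀, scale₀) seeded
  by Gumbel moment matching of log-values. Up to five jittered restarts
  on non-convergence, then a `FitError` with diagnostics.
* **mle** — `scipy.stats.gumbel_r.fit` / `scipy.stats.invweibull.fit` on
  the raw maxima, with R² reported post hoc against the histogram. The
  three-parameter histogram fit lets shape and location trade off (it can
  report α far from the tail index at an excellent R²); MLE pins the
  shape, so shape-recovery checks use it.

R² is `1 − SS_res/SS_tot` about the observed mean, requiring ≥ 3 points
and nonzero variance; a zero-variance maxima sample (fixed time constant)
raises `DegenerateSampleError` rather than fitting. A KS statistic
against the fitted law is reported alongside.

`theoretical_max_params` provides the closed-form check for the
exponential case: the maximum of n shifted exponentials of scale s is
Gumbel(μ + s·ln n, s). The per-trial spike count is random, so the
observed mean block size stands in for n — an approximation accurate to
first order in var(n)/n̄², well below the 5%-of-scale tolerance used in
the tests.

## Reference experiments and problem sizes

Two canonical configurations are built in: exponential intervals
(μ = 20 ms, scale 5 ms; reference 100,000 trials) fit by Gumbel, and
Pareto intervals (μ = 20 ms, tail index 20 or 7.5; reference 1,000,000
trials) fit by Fréchet. The package runs them at a default
`scale_factor = 0.1` (10,000 and 100,000 trials respectively) — sizes at
which the R² ≥ 0.99 conclusions are stable across seeds (observed
R² ≈ 0.998 and 0.9999) while a full run completes in seconds to tens of
seconds on one core. Trial i uses substream i of the master seed
(`SeedSequence` spawn keys over PCG64), so runs are bit-reproducible and
any single trial can be resimulated in isolation.

Convergence to the limit laws is verified two ways: simulated
standardized maxima (m = 10⁵) are compared to the limit by KS distance,
and the distributional distance `sup |Fⁿ(a_n x + b_n) − G(x)|` is
evaluated exactly on a fine grid through the `Fⁿ` machinery. At m = 10⁵
the KS sampling floor (~0.003) exceeds the distributional bias beyond
n ≈ 100 (bias ~0.0003 at n = 1000), so the strict decrease across
n ∈ {10, 100, 1000} is asserted on the exact distance and the sampled
statistic is asserted where it is informative (decrease from n = 10 to
100, and the < 0.05 bound at n = 1000).

## What the generator does and does not emulate

The synthetic trials realise the model's own assumptions: i.i.d.
intervals, stationary rate, perfectly observed spike times on (in ode
mode) a 1 ms grid. Real recordings violate several of these —
refractory-period correlations, nonstationary drive, measurement jitter,
finite recording windows that censor the longest delays — and parallel
fan-in from many neurons superposes processes rather than chaining them.
Passing tests therefore demonstrate the internal consistency of the
model-to-EVT chain, not that any particular biological preparation is in
a given domain of attraction; applying the pipeline to measured delays
would require the fitting layer only (it accepts user-supplied interval
or maxima samples) plus judgement about those violations.

## Numerical choices and limitations

* Forward Euler at Δt = 1 ms, no adaptive stepping; the ode-mode interval
  carries an O(Δt) quantisation plus discretisation bias, tested against
  the exact discrete recurrence and the Δt → 0 limit.
* Strict `V > θ` firing; on-grid equality is defined as non-firing.
* Histograms use a deterministic `⌊min⌋` bin origin; fits are invariant
  to sub-bin origin shifts within stated tolerances (tested).
* Pareto tail index σ ≤ 1 (infinite mean) is sampled correctly but
  flagged with a warning; the experiments do not use it.
* The Fréchet histogram fit's shape/location trade-off is a genuine
  identifiability limit of three-parameter fitting on a narrow histogram;
  use MLE when the tail index itself is the quantity of interest.
* CSV serialisation uses fixed 9-decimal precision so file round-trips
  are exact at the 1e−9 ms level.
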