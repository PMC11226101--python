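# spikevt

Extreme-value statistics of inter-spike intervals in a stochastic leaky
integrate-and-fire (LIF) neuron.

## The problem

Transmission of a spike between two neurons — down the axon, across the
synapse, into the postsynaptic cell — takes a fluctuating amount of time.
Treating successive spike arrival times `T_i` as a point process, the
waiting times `d_i = T_i − T_{i−1}` become random variables, and the
per-recording maximum delay `d_max` is the natural indicator of worst-case
transmission lag. Extreme value theory (EVT) says the distribution of such
block maxima, if it stabilises at all, must be one of exactly three laws —
Gumbel, Fréchet or Weibull — so the histogram of `d_max` over many
recordings is a principled, low-dimensional summary of a neuron's delay
behaviour.

`spikevt` is for computational neuroscientists and biostatisticians who
want to simulate this mechanism and verify or exploit the EVT limits:
it couples a stochastic LIF simulator to a block-maxima / histogram /
limit-law-fitting pipeline.

## The model

The membrane potential follows the LIF equation

```
ξ dV/dt = −(V − V_rest) + R·I_ext,    V > θ  ⇒  spike, V ← V_reset,
```

integrated by forward Euler (Δt = 1 ms, 1000 steps per trial) with the
standard constants (V_rest, V_reset, θ, R, I_ext) = (−65 mV, −65 mV,
−55 mV, 1 MΩ, 12 nA). The classical model uses a fixed time constant τ and
fires strictly periodically; here ξ is **redrawn after every spike** from

* a shifted exponential, `ξ = μ − s·log U`, or
* a Pareto law, `ξ = μ·U^(−1/σ)`,

(inverse-transform sampling, `U ~ Uniform(0,1]`), which makes the
inter-spike intervals i.i.d. random variables. An exponential synapse
current `I_s(t) = I_s(0)e^(−t/τ_s)` gates the reset (a spike is accepted
only once `I_s < I_s(0)/e`), modelling the chemical synaptic delay; at the
default τ_s = 2 ms it never alters the spike statistics.

For i.i.d. intervals with population CDF `F`, the per-trial maximum has CDF
`F^n` exactly, and with norming constants `(a_n, b_n) = (1, ln n)` an
exponential interval law lands in the Gumbel domain,

```
G(x) = exp[−exp(−x)],
```

while a Pareto law with tail index α lands, with `(n^{1/α}, 0)`, in the
Fréchet domain `G(x) = exp(−x^{−α})`. The package simulates many trials,
histograms the per-trial maxima (masses summing to one), fits the matching
limit law by nonlinear least squares on the histogram (or maximum
likelihood on the raw maxima) and reports R² and a Kolmogorov–Smirnov
distance.

## Worked example

```python
from spikevt import reproduce_paper, theoretical_max_params, TimeConstantModel

result = reproduce_paper("fig3", scale_factor=0.1, master_seed=1)
tc = TimeConstantModel("exponential", 20.0, 5.0, convention="scale")
loc, scale = theoretical_max_params(tc, result.maxima.mean_block_size)
print(result.fit.location, result.fit.scale, result.fit.r_squared)
```

prints (10,000 trials of 1000 ms, exponential intervals, μ = 20 ms,
scale 5 ms):

```
fitted Gumbel: location 38.36 ms, scale 4.83 ms
closed form:   location 38.39 ms, scale 5.00 ms
R^2 = 0.9983
```

The fitted location sits at `μ + 5·ln n̄` for the observed mean spike count
n̄ ≈ 39.5 per trial — the closed-form Gumbel maximum of shifted
exponentials — and R² ≥ 0.99 confirms the Gumbel shape of the maxima
histogram. The scripts in `examples/` run this and the Pareto → Fréchet
case (where the fitted Fréchet shape recovers the Pareto tail index:
20.4 vs 20), a single-trial simulation in both modes, and an exact
norming-constant convergence table.

A thin CLI wraps the same library calls:

```
spikevt reproduce fig3 --scale 0.1 --seed 1 --out-dir out/
spikevt simulate --trials 100 --seed 0 --out-dir out/
spikevt maxima out/trains.csv --out out/maxima.csv
spikevt fit out/maxima.csv --family gumbel
```

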