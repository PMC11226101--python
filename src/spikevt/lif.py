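"""Stochastic leaky integrate-and-fire (LIF) neuron with threshold-reset
dynamics and post-spike resampling of the membrane time constant.

The membrane potential obeys

    xi dV/dt = -(V - V_rest) + R * I_ext,

integrated by explicit forward Euler on a fixed grid.  When ``V`` exceeds
the threshold ``theta`` (strict inequality) *and* the synaptic gate is open,
a spike is recorded, ``V`` is reset to ``V_reset``, the synapse current is
reset, and a fresh time constant ``xi`` is drawn from the configured
:class:`~spikevt.sampling.TimeConstantModel`.  The synaptic gate models the
chemical delay at the synapse as an exponentially decaying current
``I_s(t) = I_s(0) * exp(-t/tau_s)``; a new spike is only accepted once the
current has decayed below ``omega = I_s(0)/e``, i.e. once at least ``tau_s``
has elapsed since the previous spike.  With the default parameters the gate
never bites (intervals are tens of ms, ``tau_s`` is 2 ms), matching the
observation that in a one-directional single-neuron chain the synapse does
not alter the spike statistics.

Two simulation modes are provided:

``ode``
    Mechanistic mode: integrate the Euler recurrence step by step.  For a
    drawn ``xi`` the inter-spike interval is the deterministic grid
    crossing time, approximately ``xi * ln 6`` under the default constants.

``direct``
    Interval-sampling mode: the inter-spike intervals ``d_i`` are drawn
    directly from the time-constant law and accumulated into spike times
    until the simulated window ``n_steps * dt`` is exhausted.  This is the
    mode used for the extreme-value experiments, where the interval law
    itself (shifted exponential or Pareto) is the object of study.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .sampling import RandomStream, TimeConstantModel, sample_xi

__all__ = [
    "LIFParameters",
    "SynapseModel",
    "SpikeTrain",
    "SilentNeuronWarning",
    "euler_step",
    "analytic_first_spike_time",
    "synapse_current",
    "extract_intervals",
    "simulate_trial",
]


class SilentNeuronWarning(UserWarning):
    """Emitted when a configuration cannot reach threshold (no spikes)."""


@dataclass(frozen=True)
class LIFParameters:
    """Electrophysiological constants and integration grid.

    Defaults are the standard single-neuron benchmark values:
    ``(V_rest, V_reset, theta, R, I_ext) = (-65 mV, -65 mV, -55 mV,
    1.0 MOhm, 12 nA)`` with ``dt = 1 ms`` and 1000 steps (1000 ms of
    physical time per trial).  ``R * I_ext`` is in mV when ``R`` is in MOhm
    and ``I_ext`` in nA (12 mV here), so the potential asymptotes to
    ``V_rest + R*I_ext = -53 mV``, above the -55 mV threshold: the neuron
    fires periodically.
    """

    v_rest: float = -65.0
    v_reset: float = -65.0
    v_init: float = -65.0
    theta: float = -55.0
    r: float = 1.0
    i_ext: float = 12.0
    dt: float = 1.0
    n_steps: int = 1000

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if int(self.n_steps) < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        object.__setattr__(self, "n_steps", int(self.n_steps))

    @property
    def drive(self) -> float:
        """Steady-state depolarisation ``R * I_ext`` in mV."""
        return self.r * self.i_ext

    @property
    def v_asymptote(self) -> float:
        """Equilibrium potential ``V_rest + R * I_ext`` in mV."""
        return self.v_rest + self.drive

    @property
    def can_spike(self) -> bool:
        """Whether the asymptote lies above threshold (firing possible)."""
        return self.v_asymptote > self.theta

    @property
    def total_time(self) -> float:
        """Physical duration of one trial, ``n_steps * dt`` in ms."""
        return self.n_steps * self.dt


@dataclass(frozen=True)
class SynapseModel:
    """Exponential synapse-current decay ``I_s(t) = i_s0 * exp(-t/tau_s)``.

    ``omega``, the gate level below which the synapse is ready for the next
    spike, is pinned to ``i_s0 / e`` (the current after one decay time), so
    only the decay time ``tau_s`` is a free parameter.  ``tau_s`` defaults
    to 2 ms: the synaptic current decays essentially immediately compared
    with the tens-of-ms membrane dynamics.
    """

    tau_s: float = 2.0
    i_s0: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not self.tau_s > 0:
            raise ValueError(f"tau_s must be > 0, got {self.tau_s}")
        if not self.i_s0 > 0:
            raise ValueError(f"i_s0 must be > 0, got {self.i_s0}")

    @property
    def omega(self) -> float:
        """Gate threshold ``i_s0 * e**-1``."""
        return self.i_s0 * math.exp(-1.0)


@dataclass(frozen=True)
class SpikeTrain:
    """One trial's spike times ``T_i`` and inter-spike intervals ``d_i``.

    Under the from-zero convention the first interval is ``T_1 - 0`` (the
    initial condition ``V_init = V_reset`` makes the first firing cycle
    statistically identical to later ones), so ``len(intervals) ==
    len(spike_times)``.  Spike times are strictly increasing and, in
    ``ode`` mode, multiples of ``dt``; in ``direct`` mode they are
    continuous.  ``xi_draws`` optionally records the sequence of time
    constants used (one per interval, plus the final unused draw in ode
    mode), for mechanistic checks.
    """

    trial_id: int
    spike_times: np.ndarray
    intervals: np.ndarray
    params_digest: str = ""
    xi_draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        ivals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "spike_times", times)
        object.__setattr__(self, "intervals", ivals)
        if times.size != ivals.size:
            raise ValueError("spike_times and intervals must have equal length")
        if times.size:
            if times[0] <= 0 or np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be positive and strictly increasing")
            if np.any(ivals <= 0):
                raise ValueError("intervals must all be positive")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def is_empty(self) -> bool:
        return self.spike_times.size == 0

    def max_interval(self) -> float:
        """Largest inter-spike interval ``d_max`` (ms); errors when empty."""
        if self.is_empty:
            raise ValueError("empty spike train has no maximum interval")
        return float(self.intervals.max())


def euler_step(v: float, xi: float, p: LIFParameters) -> float:
    """One explicit forward-Euler step of the membrane equation.

    Returns ``v + (dt/xi) * (-(v - v_rest) + R*I_ext)``.
    """
    if not xi > 0:
        raise ValueError(f"time constant must be > 0, got {xi}")
    return v + (p.dt / xi) * (-(v - p.v_rest) + p.drive)


def analytic_first_spike_time(xi: float, p: LIFParameters) -> float:
    """Continuous-time threshold-crossing time from rest for a given ``xi``.

    Solving the linear membrane ODE from ``V(0) = V_rest`` gives
    ``t* = xi * ln( R*I_ext / (R*I_ext - (theta - V_rest)) )``; with the
    default constants ``t* = xi * ln 6``.  Used as the oracle for the Euler
    integration.
    """
    if not xi > 0:
        raise ValueError(f"time constant must be > 0, got {xi}")
    if not p.can_spike:
        raise ValueError(
            "silent neuron: asymptote "
            f"{p.v_asymptote} mV does not exceed threshold {p.theta} mV"
        )
    return xi * math.log(p.drive / (p.drive - (p.theta - p.v_rest)))


def synapse_current(syn: SynapseModel, t_since_spike: float) -> float:
    """Synapse current ``i_s0 * exp(-t/tau_s)`` at ``t`` ms after a spike."""
    if t_since_spike < 0:
        raise ValueError(f"elapsed time must be >= 0, got {t_since_spike}")
    return syn.i_s0 * math.exp(-t_since_spike / syn.tau_s)


def extract_intervals(spike_times, from_zero: bool = True) -> np.ndarray:
    """First-difference a strictly increasing spike-time sequence into
    inter-spike intervals.

    With ``from_zero=True`` (default) the first interval is measured from
    ``t = 0``, so the output has the same length as the input.
    """
    times = np.asarray(spike_times, dtype=float)
    if times.ndim != 1:
        raise ValueError("spike times must be a 1-d sequence")
    if times.size == 0:
        return np.empty(0, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing without duplicates")
    if from_zero:
        if times[0] <= 0:
            raise ValueError("first spike time must be positive under the from-zero convention")
        return np.diff(times, prepend=0.0)
    return np.diff(times)


def _digest(p: LIFParameters, tc: TimeConstantModel, syn: SynapseModel | None, mode: str) -> str:
    text = f"{p!r}|{tc!r}|{syn!r}|{mode}"
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def _simulate_ode(p, tc, syn, stream, trial_id, digest):
    times: list[float] = []
    xis: list[float] = []
    xi = float(sample_xi(tc, stream))
    xis.append(xi)
    v = p.v_init
    t_last: float | None = None
    gate_enabled = syn is not None and syn.enabled
    for k in range(1, p.n_steps + 1):
        t = k * p.dt
        v = euler_step(v, xi, p)
        if v > p.theta:
            if gate_enabled and t_last is not None:
                if synapse_current(syn, t - t_last) >= syn.omega:
                    continue  # synapse not yet recovered; spike deferred
            times.append(t)
            v = p.v_reset
            t_last = t
            xi = float(sample_xi(tc, stream))
            xis.append(xi)
    times_arr = np.asarray(times, dtype=float)
    return SpikeTrain(
        trial_id=trial_id,
        spike_times=times_arr,
        intervals=extract_intervals(times_arr),
        params_digest=digest,
        xi_draws=np.asarray(xis, dtype=float),
    )


def _simulate_direct(p, tc, stream, trial_id, digest):
    horizon = p.total_time
    # Every interval is >= mu for all three families, so the spike count in
    # a window of length T is bounded by T/mu: one vectorised draw suffices.
    n_max = int(math.floor(horizon / tc.mu)) + 1
    draws = np.atleast_1d(sample_xi(tc, stream, size=n_max))
    times = np.cumsum(draws)
    keep = times <= horizon
    return SpikeTrain(
        trial_id=trial_id,
        spike_times=times[keep],
        intervals=draws[keep],
        params_digest=digest,
        xi_draws=draws[keep],
    )


def simulate_trial(
    p: LIFParameters,
    tc: TimeConstantModel,
    syn: SynapseModel | None = None,
    stream: RandomStream | None = None,
    mode: str = "ode",
    trial_id: int = 0,
) -> SpikeTrain:
    """Simulate one trial of exactly ``n_steps * dt`` ms.

    Parameters
    ----------
    mode
        ``"ode"`` integrates the Euler recurrence, resampling ``xi`` after
        each spike and honouring the synaptic gate.  ``"direct"`` draws the
        inter-spike intervals ``d_i`` straight from the time-constant law
        and accumulates them into spike times until the window is
        exhausted (the synapse model is irrelevant in this mode).
    stream
        Required unless ``tc.family == "fixed"``.

    A configuration that cannot reach threshold yields an *empty* train and
    a :class:`SilentNeuronWarning`, not an exception, so parameter sweeps
    do not abort.
    """
    if mode not in ("ode", "direct"):
        raise ValueError(f"unknown mode {mode!r}; expected 'ode' or 'direct'")
    if tc.family != "fixed" and stream is None:
        raise ValueError("a RandomStream is required for stochastic time constants")
    digest = _digest(p, tc, syn, mode)
    if mode == "ode":
        if syn is None:
            syn = SynapseModel(enabled=False)
        if not p.can_spike:
            warnings.warn(
                "silent neuron: threshold unreachable, returning empty spike train",
                SilentNeuronWarning,
                stacklevel=2,
            )
            return SpikeTrain(trial_id, np.empty(0), np.empty(0), digest)
        return _simulate_ode(p, tc, syn, stream, trial_id, digest)
    if tc.family == "fixed" and stream is None:
        stream = RandomStream(0)  # unused by the fixed family
    return _simulate_direct(p, tc, stream, trial_id, digest)
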