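"""Seedable random streams and inverse-transform samplers for the
stochastic membrane time constant.

The stochastic integrate-and-fire neuron replaces the fixed membrane time
constant ``tau`` by a fresh random draw ``xi(mu, sigma)`` after every spike,
which turns the deterministic spike period into a random inter-spike
interval.  Two non-degenerate families are supported, both generated by
inverse-transform sampling from a uniform variate ``U`` in ``(0, 1]``:

shifted exponential
    ``xi = mu - scale * log(U)``, supported on ``[mu, inf)``.  ``mu`` (ms)
    locates the lower endpoint; ``sigma`` enters either as a rate
    (``scale = 1/sigma``, convention ``"literal"``) or directly as the
    e-folding scale in ms (``scale = sigma``, convention ``"scale"``).
    Both conventions yield a shifted exponential, so every downstream
    extreme-value statement holds under either reading.

Pareto
    ``xi = mu * U**(-1/sigma)``, supported on ``[mu, inf)`` with survival
    function ``P(X > x) = (mu/x)**sigma``.  ``mu`` (ms) is the scale /
    lower endpoint and ``sigma`` the dimensionless tail index; the mean is
    infinite for ``sigma <= 1`` (permitted, but flagged with a warning).

A third degenerate family, ``"fixed"``, returns ``mu`` deterministically and
recovers the classical constant-``tau`` neuron.

Uniform draws are taken from the half-open interval ``(0, 1]`` — zero is
excluded by construction so that ``log(U)`` and ``U**(-1/sigma)`` are always
finite, with no ad-hoc clamping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAMILIES",
    "CONVENTIONS",
    "RandomStream",
    "TimeConstantModel",
    "make_stream",
    "sample_exponential_xi",
    "sample_pareto_xi",
    "sample_xi",
]

FAMILIES = ("fixed", "exponential", "pareto")
CONVENTIONS = ("literal", "scale")


class RandomStream:
    """Reproducible uniform random stream with derivable substreams.

    Wraps a PCG64 generator keyed by ``(seed, spawn_key)`` through
    :class:`numpy.random.SeedSequence`.  Two streams built with the same
    seed (and spawn key) produce identical draw sequences; substreams
    derived with distinct keys are statistically independent yet
    individually reproducible, which is how per-trial randomness is
    organised in the experiment layer.

    Uniform draws lie in ``(0, 1]`` (zero excluded, one included).
    """

    def __init__(self, seed: int, spawn_key: tuple[int, ...] = ()) -> None:
        seed = int(seed)
        if seed < 0:
            raise ValueError(f"seed must be >= 0, got {seed}")
        self.seed = seed
        self.spawn_key = tuple(int(k) for k in spawn_key)
        self._seq = np.random.SeedSequence(self.seed, spawn_key=self.spawn_key)
        self._gen = np.random.Generator(np.random.PCG64(self._seq))

    @property
    def generator(self) -> np.random.Generator:
        """The underlying :class:`numpy.random.Generator` (advances state)."""
        return self._gen

    def uniform(self, size=None):
        """Draw uniforms on the half-open interval ``(0, 1]``.

        Returns a scalar ``float`` when ``size`` is None, else an ndarray.
        """
        # Generator.random() covers [0, 1); the reflection maps it to (0, 1].
        u = 1.0 - self._gen.random(size)
        if size is None:
            return float(u)
        return u

    def substream(self, k: int) -> "RandomStream":
        """Derive the ``k``-th independent substream, reproducible from
        ``(seed, spawn_key + (k,))`` alone."""
        if k < 0:
            raise ValueError(f"substream index must be >= 0, got {k}")
        return RandomStream(self.seed, self.spawn_key + (int(k),))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RandomStream(seed={self.seed}, spawn_key={self.spawn_key})"


def make_stream(seed: int) -> RandomStream:
    """Create the master :class:`RandomStream` for a given nonnegative seed."""
    return RandomStream(seed)


@dataclass(frozen=True)
class TimeConstantModel:
    """The law ``xi(mu, sigma)`` that replaces the membrane time constant.

    Parameters
    ----------
    family
        One of ``"fixed"``, ``"exponential"``, ``"pareto"``.
    mu
        Location / lower endpoint in ms; also the deterministic value for
        ``family="fixed"``.  Must be positive.
    sigma
        Second parameter: rate-or-scale for the exponential family (see
        ``convention``), dimensionless tail index for the Pareto family.
        Ignored by ``family="fixed"``.  Must be positive.
    convention
        How ``sigma`` enters the exponential formula: ``"literal"`` uses
        scale ``1/sigma`` (sigma read as a rate), ``"scale"`` uses scale
        ``sigma`` (sigma read as an e-folding time in ms).
    """

    family: str
    mu: float
    sigma: float = 1.0
    convention: str = "literal"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.convention not in CONVENTIONS:
            raise ValueError(
                f"unknown convention {self.convention!r}; expected one of {CONVENTIONS}"
            )
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.family == "pareto" and self.sigma <= 1:
            warnings.warn(
                f"Pareto tail index sigma={self.sigma} <= 1: the mean "
                "inter-spike interval is infinite",
                UserWarning,
                stacklevel=2,
            )

    @property
    def exponential_scale(self) -> float:
        """Scale (ms) of the exponential excess over mu: 1/sigma or sigma."""
        return 1.0 / self.sigma if self.convention == "literal" else self.sigma

    @property
    def has_finite_mean(self) -> bool:
        return not (self.family == "pareto" and self.sigma <= 1)

    def mean(self) -> float:
        """Analytic mean of the law (ms); ``inf`` for Pareto with sigma <= 1."""
        if self.family == "fixed":
            return self.mu
        if self.family == "exponential":
            return self.mu + self.exponential_scale
        if self.sigma <= 1:
            return float("inf")
        return self.mu * self.sigma / (self.sigma - 1.0)


def _validated_uniforms(u):
    arr = np.asarray(u, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("uniform draws must lie in the half-open interval (0, 1]")
    return arr


def _match_input(out: np.ndarray, u) -> "float | np.ndarray":
    if np.ndim(u) == 0:
        return float(out)
    return out


def sample_exponential_xi(model: TimeConstantModel, u):
    """Inverse-transform a uniform draw into a shifted-exponential time
    constant: ``mu - scale * log(u)`` with scale per ``model.convention``.

    Accepts a scalar or array of uniforms in ``(0, 1]``; the result is
    always >= ``mu``.
    """
    if model.family != "exponential":
        raise ValueError(f"model family is {model.family!r}, not 'exponential'")
    arr = _validated_uniforms(u)
    out = model.mu - model.exponential_scale * np.log(arr)
    return _match_input(out, u)


def sample_pareto_xi(model: TimeConstantModel, u):
    """Inverse-transform a uniform draw into a Pareto time constant:
    ``mu * u**(-1/sigma)``, so that ``P(X > x) = (mu/x)**sigma`` for
    ``x >= mu``.
    """
    if model.family != "pareto":
        raise ValueError(f"model family is {model.family!r}, not 'pareto'")
    arr = _validated_uniforms(u)
    out = model.mu * arr ** (-1.0 / model.sigma)
    return _match_input(out, u)


def sample_xi(model: TimeConstantModel, stream: RandomStream, size=None):
    """Draw time constants from the configured family.

    ``family="fixed"`` returns ``mu`` exactly (no stream state consumed);
    the stochastic families consume one uniform per draw.
    """
    if model.family == "fixed":
        if size is None:
            return float(model.mu)
        return np.full(size, float(model.mu))
    u = stream.uniform(size)
    if model.family == "exponential":
        return sample_exponential_xi(model, u)
    return sample_pareto_xi(model, u)
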