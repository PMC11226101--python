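"""Deterministic small files for tests and demos.

All fixtures are generated programmatically from a seed; nothing is
shipped as data.  The maxima fixtures are synthetic draws from the target
limit laws (not simulated spike trains) and are labelled as such.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lif import LIFParameters, simulate_trial
from .sampling import TimeConstantModel, make_stream

__all__ = ["FIXTURE_KINDS", "make_fixture"]

FIXTURE_KINDS = ("tiny_train", "gumbel_maxima", "frechet_maxima")

_FMT = "%.9f"


def make_fixture(kind: str, seed: int = 0, out_dir=".") -> Path:
    """Write one deterministic fixture file and return its path.

    ``tiny_train``
        A 10-spike train from the fixed-time-constant neuron (CSV:
        trial_id, spike_time_ms).
    ``gumbel_maxima``
        500 synthetic draws from Gumbel(location=40 ms, scale=5 ms)
        (CSV: trial_id, d_max_ms).
    ``frechet_maxima``
        500 synthetic draws from Frechet(alpha=20, scale=24 ms,
        location=0) (CSV: trial_id, d_max_ms).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stream = make_stream(seed)
    if kind == "tiny_train":
        # 35-step period under the defaults; 355 steps -> exactly 10 spikes
        p = LIFParameters(n_steps=355)
        tc = TimeConstantModel("fixed", mu=20.0)
        train = simulate_trial(p, tc, stream=stream, mode="ode")
        df = pd.DataFrame({
            "trial_id": np.zeros(train.n_spikes, dtype=int),
            "spike_time_ms": train.spike_times,
        })
        path = out_dir / f"tiny_train_seed{seed}.csv"
    elif kind == "gumbel_maxima":
        u = stream.uniform(size=500)
        values = 40.0 - 5.0 * np.log(-np.log(u))
        df = pd.DataFrame({"trial_id": np.arange(500), "d_max_ms": values})
        path = out_dir / f"gumbel_maxima_synthetic_seed{seed}.csv"
    elif kind == "frechet_maxima":
        u = stream.uniform(size=500)
        values = 24.0 * (-np.log(u)) ** (-1.0 / 20.0)
        df = pd.DataFrame({"trial_id": np.arange(500), "d_max_ms": values})
        path = out_dir / f"frechet_maxima_synthetic_seed{seed}.csv"
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    df.to_csv(path, index=False, float_format=_FMT)
    return path
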