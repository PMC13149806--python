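"""Seed-stream management.

All randomness in the package flows from a single integer seed. Each pipeline
stage draws from a named substream so that adding draws to one stage never
perturbs another.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: stream name -> spawn key. Append-only; never reorder.
_STREAMS = {
    "attributes": 0,
    "weights": 1,
    "rating_noise": 2,
    "pairing": 3,
    "true_params": 4,
    "trials_ddm": 5,
    "trials_maddm": 6,
    "trials_stddm": 7,
    "fit_starts": 8,
    "misc": 9,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``."""
    try:
        key = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown random stream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
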