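"""Deterministic seed fan-out.

Every stochastic stage of the pipeline derives its random stream from a
single top-level seed plus a tuple of string/int tags naming the stage, so
that whole runs are reproducible while stages stay statistically independent.
"""

from __future__ import annotations

import hashlib

import numpy as np


def spawn_seed(seed: int, *tags) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a stage tag tuple."""
    payload = repr((int(seed),) + tuple(tags)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int, *tags) -> np.random.Generator:
    """A fresh Generator for stage ``tags`` under top-level ``seed``."""
    return np.random.default_rng(spawn_seed(seed, *tags))
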