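"""Reproducible random streams derived from a single master seed.

Every stochastic component (stimulus noise paths, observation noise, the
Monte-Carlo samplers, ABC SMC) draws from a substream derived from the master
seed and a short stream name.  The derivation rule is
``SeedSequence([master, crc32(name), index])``: deterministic, documented, and
collision-resistant enough for the handful of named streams used here.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(master_seed: int, name: str, index: int = 0) -> np.random.SeedSequence:
    if master_seed is None:
        raise ValueError("a master seed is required for reproducible runs")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence([int(master_seed), int(tag), int(index)])


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return an independent ``Generator`` for stream *name* under *master_seed*."""
    return np.random.default_rng(child_seed_sequence(master_seed, name, index))
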