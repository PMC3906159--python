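"""Deterministic seed splitting.

Every stochastic routine in the package takes one integer seed.  Pipeline
stages derive their own child seeds from the master seed with
:func:`child_seed`, keyed by a stable stage label, so any stage can be
re-run in isolation with a result identical to its in-pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(master_seed: int, label: str) -> int:
    """Derive a stage seed (< 2**31) from a master seed and a text label."""
    tag = zlib.crc32(label.encode("utf-8"))
    mixed = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, tag])
    return int(mixed.generate_state(1, dtype=np.uint64)[0] % _MOD)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    """Generator seeded from ``child_seed(master_seed, label)``."""
    return np.random.default_rng(child_seed(master_seed, label))
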