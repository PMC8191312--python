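"""Deterministic child-seed derivation.

Every stochastic stage derives its own seed from the master seed and its
stage name, so adding or removing a stage never perturbs the random
streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(master: int, name: str) -> int:
    """Derive a stable child seed (< 2**31) from a master seed and a label."""
    mix = (int(master) * 0x9E3779B1 + zlib.crc32(name.encode())) % _MOD
    return int(mix)


def rng_for(master: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, name))
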