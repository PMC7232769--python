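"""Deterministic child-stream derivation from a single global seed.

Every stochastic operation in the package draws from a generator derived
from ``(seed, operation_name)`` so that adding or reordering operations in
a pipeline never perturbs the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _name_key(name: str) -> int:
    # stable across processes and Python versions (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def child_seed(seed: int, name: str) -> int:
    """A reproducible 31-bit child seed for the named operation."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A Generator seeded from (seed, name)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)
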