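"""Named random streams derived from one master seed.

Every stochastic stage of the pipeline draws from its own named stream so
that changing, say, the number of permutations in the statistics stage does
not perturb the synthetic data, and vice versa.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_stream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Deterministically derive a 31-bit child seed for stream `name`."""
    mix = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF])
    return int(mix.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def seed_stream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named stream of a master seed."""
    return np.random.default_rng(child_seed(seed, name))
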