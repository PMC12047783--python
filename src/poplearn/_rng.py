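"""Named, reproducible random streams.

Every stochastic stage of the pipeline (spike generation, tie-breaking,
motor noise, task sampling, permutations, optimizer restarts) draws from
its own child stream of a single user-supplied seed, so that runs are
reproducible bit-for-bit and stages can be re-run independently.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["named_streams", "child_seed", "as_rng"]


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from ``seed`` and a label."""
    return (int(seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1)


def named_streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Return one independent ``Generator`` per name, derived from ``seed``."""
    return {n: np.random.default_rng(child_seed(seed, n)) for n in names}


def as_rng(rng) -> np.random.Generator:
    """Coerce ``None`` | int | Generator to a ``numpy.random.Generator``."""
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
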