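"""Deterministic random-stream derivation.

Every stochastic operation takes a single integer seed and derives an
independent child stream per named sub-task, so that a root seed fixes the
whole pipeline bit-exactly while sub-tasks stay statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, *names: str) -> int:
    """Derive a child seed below 2**31 from ``seed`` and a path of names.

    The derivation is a CRC32 over the name path mixed into a SeedSequence,
    so ``child_seed(s, "a")`` and ``child_seed(s, "b")`` are decorrelated
    and stable across sessions.
    """
    key = zlib.crc32("/".join(names).encode())
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def child_rng(seed: int, *names: str) -> np.random.Generator:
    """A ``numpy`` Generator seeded from ``seed`` and a path of names."""
    return np.random.default_rng(child_seed(seed, *names))
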