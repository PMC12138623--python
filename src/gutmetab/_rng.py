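"""Seed fan-out: one independent RNG stream per output artifact.

Every stochastic component derives its generator from a master seed plus a
stable string label, so adding a new output stream never perturbs existing
ones and a whole run is reproducible from a single integer.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def child_seed(seed: int, label: str) -> int:
    """Derive a deterministic 31-bit child seed from (seed, label)."""
    return (int(seed) * 0x9E3779B1 + zlib.crc32(label.encode("utf-8"))) % (2**31 - 1)


def stream(seed: int, label: str) -> np.random.Generator:
    """Return an independent ``numpy`` Generator for one labelled stream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))]))
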