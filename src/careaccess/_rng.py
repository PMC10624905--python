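"""Seeded substream derivation.

A single master seed drives every stochastic stage. Substreams are derived by
hashing a tuple of string keys with SHA-256 (stable across processes and
Python versions, unlike the builtin ``hash``), so adding a country or a
quarter to a scenario does not perturb the draws of any other slice.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "laplace"]


def _digest(*keys: object) -> int:
    data = "\x1f".join(str(k) for k in keys).encode("utf-8")
    return int.from_bytes(hashlib.sha256(data).digest()[:8], "little")


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed) & 0x7FFFFFFF, _digest(*keys)])
    )


def laplace(rng: np.random.Generator, scale: float, size=None):
    """Laplace(0, scale) via inverse-CDF from a uniform stream.

    Inverse-CDF sampling keeps the draw reproducible for a given generator
    state regardless of how the library's native laplace sampler is
    implemented.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    u = rng.uniform(-0.5, 0.5, size=size)
    return -scale * np.sign(u) * np.log1p(-2.0 * np.abs(u))
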