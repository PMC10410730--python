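"""Seed fan-out helpers.

A single global seed is expanded into independent per-component seeds via
``numpy.random.SeedSequence.spawn``-style derivation keyed on a component
name, so that experiments are reproducible piecewise.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(seed: int, name: str) -> int:
    """Derive a component seed from a global seed and a component name.

    Deterministic: SHA-256 of ``"{seed}:{name}"`` truncated to 32 bits.
    """
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def rng_for(seed: int, name: str) -> np.random.Generator:
    """A ``numpy`` generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(seed, name))
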