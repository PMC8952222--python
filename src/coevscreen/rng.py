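"""Deterministic random-stream derivation.

Every stochastic component draws from a generator derived from the global
seed plus a stable string/int path (protein pair id, direction, site pair).
Results are therefore independent of scheduling, worker count, and the order
in which inputs are listed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _tag_int(tag: str) -> int:
    return int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")


def derive_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """A child generator determined by (seed, tags...)."""
    entropy = [int(seed)] + [t if isinstance(t, int) else _tag_int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_seed(seed: int, *tags: str | int) -> int:
    """A derived integer seed below 2**31, for APIs that take plain seeds."""
    return int(derive_rng(seed, *tags).integers(2**31))
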