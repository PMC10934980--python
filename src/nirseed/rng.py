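"""Seeding discipline.

All randomness in the package flows from a single integer seed through
named stages, so adding a stage never perturbs the stream of an existing
one, and two runs with the same seed are bit-identical.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng", "as_rng"]


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a global seed and a name."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def derive_rng(seed: int, stage: str) -> np.random.Generator:
    """A fresh generator for a named stage of a seeded run."""
    return np.random.default_rng(derive_seed(seed, stage))


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
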