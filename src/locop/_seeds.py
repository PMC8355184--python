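"""Deterministic child-seed derivation.

Every stochastic stage derives its RNG from (global seed, stage tokens) via a
stable cryptographic hash, so stages are reproducible in isolation and results
do not depend on gene iteration order or parallel scheduling.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(global_seed: int, *tokens: object) -> int:
    """Stable seed in [0, 2^31) derived from a global seed plus string tokens."""
    key = "|".join([str(int(global_seed)), *(str(t) for t in tokens)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)


def derive_rng(global_seed: int, *tokens: object) -> np.random.Generator:
    """Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(global_seed, *tokens))
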