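"""Seed derivation and small shared helpers.

All randomness flows from a single master seed. Child seeds for stages,
regions, chains and permutations are derived with a stable cryptographic
hash of (master_seed, *tokens), so adding one stage or region never
perturbs the random stream of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

_SEED_MOD = 2**31 - 1


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Deterministic child seed from a master seed and context tokens.

    Stable across processes and Python versions (unlike builtin hash()).
    The result is a non-negative int below 2**31 - 1.
    """
    payload = repr((int(master_seed),) + tuple(tokens)).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "little") % _SEED_MOD


def rng_for(master_seed: int, *tokens: object) -> np.random.Generator:
    """A numpy Generator seeded from derive_seed(master_seed, *tokens)."""
    return np.random.default_rng(derive_seed(master_seed, *tokens))


def as_region_array(value, n_regions: int, name: str) -> np.ndarray:
    """Broadcast a scalar or validate a length-n vector of per-region values."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_regions, float(arr))
    if arr.shape != (n_regions,):
        raise ValueError(
            f"{name} must be a scalar or a length-{n_regions} vector, got shape {arr.shape}"
        )
    return arr.copy()
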