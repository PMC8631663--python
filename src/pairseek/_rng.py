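"""Counter-based random streams keyed by stable identities.

The stability-selection engine needs per-iteration, per-pair and per-sample
random draws (pair orientation, randomization of zero/zero samples) that are

* reproducible from a single master seed,
* independent across iterations, and
* keyed by the *identity* of a taxon pair (its sorted name pair) and of a
  sample (its name), so that permuting the column order of the input table
  permutes the results without changing them.

A splitmix64-style integer hash gives all of that and vectorizes over numpy
uint64 arrays, which a per-pair `numpy.random.Generator` would not.
"""

from __future__ import annotations

import hashlib

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_U64 = np.uint64


def mix(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer; bijective on uint64, vectorized."""
    x = np.asarray(x, dtype=np.uint64).copy()
    x ^= x >> _U64(30)
    x *= _MIX1
    x ^= x >> _U64(27)
    x *= _MIX2
    x ^= x >> _U64(31)
    return x


def combine(*parts) -> np.ndarray:
    """Fold any number of (broadcastable) uint64 keys into one key."""
    acc = np.asarray(np.uint64(0))
    for p in parts:
        p = np.asarray(p, dtype=np.uint64)
        acc = mix(acc ^ (p + _GOLDEN))
    return acc


def name_key(name: str) -> np.uint64:
    """Stable 64-bit key for a string identifier (blake2b, platform-free)."""
    digest = hashlib.blake2b(str(name).encode("utf-8"), digest_size=8).digest()
    return np.uint64(int.from_bytes(digest, "little"))


def name_keys(names) -> np.ndarray:
    return np.array([name_key(n) for n in names], dtype=np.uint64)


def pair_keys(key_i: np.ndarray, key_j: np.ndarray) -> np.ndarray:
    """Symmetric key for unordered pairs: invariant to swapping i and j."""
    lo = np.minimum(key_i, key_j)
    hi = np.maximum(key_i, key_j)
    return combine(lo, hi)


def uniforms(keys: np.ndarray) -> np.ndarray:
    """Map uint64 keys to floats in [0, 1) with 53-bit resolution."""
    return (mix(keys) >> _U64(11)).astype(np.float64) * (2.0 ** -53)
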