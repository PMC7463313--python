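"""Shared numerical helpers: seeding, distances, degree/metre conversion."""

from __future__ import annotations

import hashlib

import numpy as np

#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEG = 111_194.0

#: mean Earth radius, metres
EARTH_RADIUS_M = 6_371_000.0


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed by hashing the stage name.

    Stable across processes and Python versions (uses SHA-256, not ``hash``),
    and kept below 2**31 so it fits any RNG seed type.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int | None, stage: str | None = None) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    if stage is not None:
        seed = derive_seed(seed, stage)
    return np.random.default_rng(seed)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees.

    Broadcasts over array inputs.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * (EARTH_RADIUS_M / 1000.0) * np.arcsin(np.sqrt(a))


def fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Fix eigenvector sign: the largest-magnitude loading of each column is
    made positive (first occurrence wins on ties). Reproducible across
    linear-algebra backends."""
    vectors = np.array(vectors, dtype=float, copy=True)
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            vectors[:, j] = -col
    return vectors
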