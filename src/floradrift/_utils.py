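"""Shared helpers: deterministic seed splitting and small validators."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & MAX_SEED
    return zlib.crc32(str(key).encode("utf-8")) & MAX_SEED


def rng_from(seed: int, *keys) -> np.random.Generator:
    """Deterministic child RNG for (seed, *keys).

    Splitting goes through ``np.random.SeedSequence`` so sibling streams
    (e.g. per cluster x replicate) are independent and reproducible across
    runs and platforms.
    """
    entropy = [int(seed) & MAX_SEED] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def check_positive(name: str, value) -> None:
    if not np.isscalar(value) or value <= 0:
        raise ValueError(f"{name} must be a positive scalar, got {value!r}")


def as_2d_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of points, got shape {pts.shape}")
    return pts
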