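"""Shared helpers: seeded random streams and small validation utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["split_rng", "check_finite_nonneg"]


def split_rng(seed: int, *keys: str) -> np.random.Generator:
    """Return an independent Generator for a named sub-stream of ``seed``.

    One global seed governs all stochastic stages; named sub-streams keep each
    stage reproducible on its own (re-running only the clustering stage with the
    same seed draws the same numbers regardless of what ran before). CRC32 of
    the key is stable across interpreter sessions, unlike ``hash(str)``.
    """
    spawn_key = tuple(zlib.crc32(k.encode("utf8")) for k in keys)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=spawn_key)
    )


def check_finite_nonneg(a: np.ndarray, name: str = "values") -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contain non-finite entries")
    if np.any(a < 0):
        raise ValueError(f"{name} contain negative entries")
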