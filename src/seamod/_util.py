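"""Shared helpers: seeded RNG derivation and small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
METERS_PER_DEG_LAT = 111_195.0  # pi * R / 180


def stage_rng(seed: int, *tags) -> np.random.Generator:
    """Derive an independent generator for a pipeline stage.

    The stream depends on the master ``seed`` and a stable hash of the
    tag tuple, so stages are decoupled: changing the number of draws in
    one stage does not perturb any other stage.
    """
    key = zlib.crc32("/".join(str(t) for t in tags).encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters (array-friendly)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def as_relative(counts):
    """Row-normalize a samples x taxa matrix to relative abundances."""
    totals = counts.sum(axis=1)
    if np.any(np.asarray(totals) == 0):
        raise ValueError("cannot normalize: sample(s) with zero total counts")
    return counts.div(totals, axis=0) if hasattr(counts, "div") else counts / totals[:, None]
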