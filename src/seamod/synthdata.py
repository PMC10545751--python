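"""Synthetic inputs with planted latitudinal structure.

Generates every input the downstream stages consume — sample metadata
along latitudinal transects, a rooted ultrametric phylogeny, a count
table with module-structured multinomial noise, and surface-drifter
trajectories advected in a prescribed convergent velocity field — so the
whole pipeline is testable without any external download.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import METERS_PER_DEG_LAT, stage_rng

__all__ = [
    "NichedModuleSpec",
    "VelocityFieldSpec",
    "default_module_specs",
    "module_asv_ids",
    "generate_metadata",
    "generate_phylogeny",
    "generate_counts",
    "generate_trajectories",
]


@dataclass(frozen=True)
class NichedModuleSpec:
    """A planted module: a group of ASVs sharing a Gaussian environmental niche.

    ``niche_center`` and ``niche_breadth`` are (latitude deg, depth m,
    temperature degC). ``mean_log_abundance`` shifts the module's overall
    weight on the log scale; ``-inf`` silences the module entirely.
    """

    module_id: int
    n_asvs: int
    niche_center: tuple[float, float, float]
    niche_breadth: tuple[float, float, float]
    mean_log_abundance: float = 0.0
    phylo_cluster: bool = True

    def __post_init__(self):
        if self.n_asvs < 1:
            raise ValueError("n_asvs must be >= 1")
        if len(self.niche_center) != 3 or len(self.niche_breadth) != 3:
            raise ValueError("niche_center / niche_breadth must have 3 entries")
        if any(b <= 0 for b in self.niche_breadth):
            raise ValueError("niche_breadth must be > 0 in every dimension")


@dataclass(frozen=True)
class VelocityFieldSpec:
    """Idealized surface velocity field with convergence zones.

    The meridional component points toward the nearest convergence
    latitude from both sides; the zonal component is uniform.
    """

    convergence_latitudes: tuple[float, ...] = (-30.0, 30.0)
    meridional_amplitude: float = 15.0  # cm/s
    zonal_amplitude: float = 5.0  # cm/s
    diffusion_sigma: float = 5.0  # km per step

    def __post_init__(self):
        if self.meridional_amplitude < 0 or self.zonal_amplitude < 0:
            raise ValueError("velocity amplitudes must be >= 0")
        if self.diffusion_sigma < 0:
            raise ValueError("diffusion_sigma must be >= 0")

    def velocity_cm_s(self, lat, lon=None):
        """(u, v) in cm/s at the given latitude(s)."""
        lat = np.asarray(lat, dtype=float)
        conv = np.asarray(self.convergence_latitudes, dtype=float)
        # nearest convergence latitude, meridional flow pulls toward it
        d = lat[..., None] - conv[None, ...] if lat.ndim else lat - conv
        nearest = conv[np.argmin(np.abs(d), axis=-1)]
        v = self.meridional_amplitude * np.clip((nearest - lat) / 10.0, -1.0, 1.0)
        u = np.full_like(v, self.zonal_amplitude)
        return u, v


def default_module_specs() -> list[NichedModuleSpec]:
    """Six planted modules: warm tropical, cold polar (N/S), frontal (N/S)
    and one broad lower-epipelagic module. Frontal niches sit at +-30 deg so
    mixed communities (and hence high local modularity) occur in the
    25-35 deg band where warm, cold and frontal niches overlap."""
    return [
        NichedModuleSpec(1, 10, (0.0, 40.0, 26.0), (10.0, 70.0, 8.0), 1.2),
        NichedModuleSpec(2, 10, (52.0, 40.0, 6.0), (7.0, 70.0, 5.0), 0.9),
        NichedModuleSpec(3, 10, (-52.0, 40.0, 6.0), (7.0, 70.0, 5.0), 0.9),
        NichedModuleSpec(4, 10, (30.0, 40.0, 15.0), (6.0, 70.0, 4.0), 0.4),
        NichedModuleSpec(5, 10, (-30.0, 40.0, 15.0), (6.0, 70.0, 4.0), 0.4),
        NichedModuleSpec(6, 10, (0.0, 230.0, 8.0), (70.0, 45.0, 10.0), 1.0),
    ]


def module_asv_ids(spec: NichedModuleSpec) -> list[str]:
    """Deterministic sequence-hash-style identifiers for a module's ASVs."""
    return [
        hashlib.md5(f"module{spec.module_id}_asv{k}".encode()).hexdigest()
        for k in range(spec.n_asvs)
    ]


# ---------------------------------------------------------------------------
# metadata


def _temperature(abs_lat, depth):
    return 2.0 + 26.0 * np.exp(-((abs_lat / 40.0) ** 2) - depth / 250.0)


def generate_metadata(
    n_stations: int,
    depths,
    oceans=("atlantic", "pacific"),
    fractions=("0.2-3",),
    seed: int = 0,
    lat_range=(-60.0, 60.0),
    station_lons=None,
) -> pd.DataFrame:
    """One row per (ocean, station, depth, size fraction).

    Temperature decreases smoothly with ``|latitude|`` and depth (plus a
    little noise); ``depth_layer`` is "upper" for depths at or above the
    station's chlorophyll-maximum proxy and "lower" below it.
    """
    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")
    depths = list(depths)
    if not depths:
        raise ValueError("depths must be non-empty")
    rng = stage_rng(seed, "metadata")
    lo, hi = lat_range
    if station_lons is None:
        station_lons = {o: -30.0 + 12.0 * i for i, o in enumerate(oceans)}

    rows = []
    for oi, ocean in enumerate(oceans):
        # small per-ocean offset so |latitude| values differ between transects
        lats = np.linspace(lo + 1.9 * oi, hi - 1.3 * oi, n_stations)
        for si, lat in enumerate(lats):
            for depth in depths:
                t = _temperature(abs(lat), depth) + rng.normal(0.0, 0.3)
                chl = (
                    0.08
                    + 2.0
                    * np.exp(-(((depth - 60.0) / 40.0) ** 2))
                    * (0.5 + 0.5 * abs(lat) / 60.0)
                    + rng.normal(0.0, 0.02)
                )
                for frac in fractions:
                    rows.append(
                        {
                            "sample_id": f"{ocean[:2].upper()}{si:02d}_{int(depth):03d}m_{frac}",
                            "ocean": ocean,
                            "station": f"{ocean[:2].upper()}{si:02d}",
                            "latitude": float(lat),
                            "longitude": float(station_lons[ocean]),
                            "depth": float(depth),
                            "fraction": frac,
                            "temperature": float(t),
                            "chlorophyll": float(max(chl, 0.01)),
                            "salinity": float(
                                34.0 + 2.0 * np.exp(-((lat / 25.0) ** 2)) - 0.002 * depth
                                + rng.normal(0.0, 0.05)
                            ),
                            "oxygen": float(200.0 + 6.0 * (30.0 - t) + rng.normal(0.0, 3.0)),
                            "nitrate": float(
                                0.5 + 25.0 * (1 - np.exp(-((abs(lat) / 45.0) ** 2)))
                                + 0.05 * depth + rng.normal(0.0, 0.5)
                            ),
                            "silicate": float(
                                1.0 + 20.0 * (1 - np.exp(-((abs(lat) / 50.0) ** 2)))
                                + 0.08 * depth + rng.normal(0.0, 0.5)
                            ),
                            "cell_counts": float(
                                1e5 * np.exp(-depth / 150.0 + rng.normal(0.0, 0.1))
                            ),
                            "generation_time": float(
                                1.0 + 10.0 * abs(lat) / 60.0 + depth / 50.0
                                + rng.normal(0.0, 0.2)
                            ),
                        }
                    )
    meta = pd.DataFrame(rows)
    # DCM proxy: depth of maximum chlorophyll per station; at/above -> upper
    dcm = meta.groupby("station", sort=False).apply(
        lambda g: g.loc[g["chlorophyll"].idxmax(), "depth"], include_groups=False
    )
    meta["depth_layer"] = np.where(
        meta["depth"].values <= dcm.loc[meta["station"]].values, "upper", "lower"
    )
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# phylogeny


class _Node:
    __slots__ = ("name", "height", "children")

    def __init__(self, name=None, height=0.0, children=()):
        self.name = name
        self.height = height
        self.children = list(children)

    def newick(self) -> str:
        def rec(node, parent_height):
            bl = parent_height - node.height
            if not node.children:
                return f"{node.name}:{bl:.6f}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6f}"

        if not self.children:
            return f"({self.name}:0.0);"
        inner = ",".join(rec(c, self.height) for c in self.children)
        return f"({inner});"


def _coalesce(units: list[_Node], heights, rng) -> _Node:
    units = list(units)
    heights = sorted(heights)
    for h in heights:
        i, j = sorted(rng.choice(len(units), size=2, replace=False))
        b = units.pop(j)
        a = units.pop(i)
        units.append(_Node(height=float(h), children=[a, b]))
    (root,) = units
    return root


def generate_phylogeny(module_specs, seed: int = 0, height: float = 1.0) -> str:
    """Rooted ultrametric Newick tree over all module ASVs.

    Modules with ``phylo_cluster=True`` form monophyletic clades (their
    tips coalesce below 0.3 * height); all other tips join at the top
    level, so clade membership carries no module signal for them.
    """
    rng = stage_rng(seed, "phylogeny")
    all_ids: list[str] = []
    top_units: list[_Node] = []
    for spec in module_specs:
        ids = module_asv_ids(spec)
        dup = set(ids) & set(all_ids)
        if dup:
            raise ValueError(f"duplicate ASV ids across modules: {sorted(dup)[:3]}")
        all_ids.extend(ids)
        tips = [_Node(name=i) for i in ids]
        if spec.phylo_cluster and len(tips) > 1:
            hs = rng.uniform(0.02 * height, 0.3 * height, size=len(tips) - 1)
            top_units.append(_coalesce(tips, hs, rng))
        else:
            top_units.extend(tips)
    if len(all_ids) < 2:
        raise ValueError("need at least 2 ASVs in total")
    if len(top_units) == 1:
        root = top_units[0]
        root.height = max(root.height, height)
    else:
        hs = rng.uniform(0.4 * height, height, size=len(top_units) - 1)
        root = _coalesce(top_units, hs, rng)
    return root.newick()


# ---------------------------------------------------------------------------
# counts


def generate_counts(
    module_specs,
    metadata: pd.DataFrame,
    depth_per_sample=None,
    seed: int = 0,
    mean_depth: float = 21_791.0,
    depth_sigma: float = 0.35,
    min_depth: int = 1000,
    asv_noise_sd: float = 0.5,
):
    """Module-structured multinomial count table.

    The expected relative abundance of an ASV in a sample is proportional
    to ``exp(mean_log_abundance + niche kernel + ASV-level noise)`` where
    the kernel is an axis-aligned Gaussian in (latitude, depth,
    temperature) evaluated at the sample's environment. Sequencing depths
    are lognormal around ``mean_depth``, truncated below at ``min_depth``.

    Returns ``(counts, membership)``: an integer samples x ASVs DataFrame
    and the planted ASV -> module_id mapping.
    """
    rng = stage_rng(seed, "counts")
    env = metadata[["latitude", "depth", "temperature"]].to_numpy(dtype=float)
    n_samples = env.shape[0]

    cols, logw_blocks, membership = [], [], {}
    for spec in module_specs:
        ids = module_asv_ids(spec)
        for a in ids:
            if a in membership:
                raise ValueError(f"duplicate ASV id {a}")
            membership[a] = spec.module_id
        cols.extend(ids)
        c = np.asarray(spec.niche_center, dtype=float)
        b = np.asarray(spec.niche_breadth, dtype=float)
        kernel = -0.5 * (((env - c) / b) ** 2).sum(axis=1)  # (n_samples,)
        noise = rng.normal(0.0, asv_noise_sd, size=(n_samples, spec.n_asvs))
        logw_blocks.append(spec.mean_log_abundance + kernel[:, None] + noise)

    logw = np.concatenate(logw_blocks, axis=1)
    logw = np.where(np.isneginf(logw), -np.inf, logw)
    mx = np.max(logw, axis=1, keepdims=True)
    if np.any(~np.isfinite(mx)):
        raise ValueError("all module weights are zero for at least one sample")
    w = np.exp(logw - mx)
    rel = w / w.sum(axis=1, keepdims=True)

    if depth_per_sample is None:
        mu = np.log(mean_depth) - 0.5 * depth_sigma**2
        d = np.maximum(rng.lognormal(mu, depth_sigma, size=n_samples), min_depth)
        depth_per_sample = d.astype(np.int64)
    else:
        depth_per_sample = np.asarray(depth_per_sample, dtype=np.int64)
        if depth_per_sample.ndim == 0:
            depth_per_sample = np.full(n_samples, int(depth_per_sample))
    if np.any(depth_per_sample <= 0):
        raise ValueError("sequencing depth must be positive for every sample")

    counts = np.vstack(
        [rng.multinomial(int(depth_per_sample[s]), rel[s]) for s in range(n_samples)]
    )
    table = pd.DataFrame(counts, index=metadata.index, columns=cols, dtype=np.int64)
    return table, membership


# ---------------------------------------------------------------------------
# drifter trajectories


def generate_trajectories(
    field_spec: VelocityFieldSpec,
    n_drifters: int,
    n_days: int,
    report_interval_h: int = 6,
    seed: int = 0,
    lat_range=(-62.0, 62.0),
    lon_range=(-45.0, 5.0),
    start_time: str = "2015-01-01",
    mean_lifetime_days: float = 365.0,
) -> pd.DataFrame:
    """Drifter fixes every ``report_interval_h`` hours (forward Euler).

    Positions advect with the field's velocity plus Gaussian step noise;
    longitudes use a ``cos(latitude)`` spherical-degrees scaling. Drifter
    lifetimes are exponential around ~1 year (floored at 30 days) and all
    records are drogued.
    """
    if n_drifters < 1:
        raise ValueError("n_drifters must be >= 1")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = stage_rng(seed, "trajectories")

    lifetimes = np.minimum(
        np.maximum(rng.exponential(mean_lifetime_days, size=n_drifters), 30.0),
        float(n_days),
    )
    steps_per_day = 24 // report_interval_h
    n_steps = n_days * steps_per_day
    dt_s = report_interval_h * 3600.0

    lat = rng.uniform(lat_range[0], lat_range[1], size=n_drifters)
    lon = rng.uniform(lon_range[0], lon_range[1], size=n_drifters)
    max_steps = np.floor(lifetimes * steps_per_day).astype(int)

    times = pd.date_range(start_time, periods=n_steps + 1, freq=f"{report_interval_h}h")
    rec_id, rec_t, rec_lat, rec_lon = [], [], [], []

    def record(step, active):
        idx = np.nonzero(active)[0]
        rec_id.append(idx)
        rec_t.append(np.full(idx.size, step))
        rec_lat.append(lat[idx].copy())
        rec_lon.append(lon[idx].copy())

    active = np.ones(n_drifters, dtype=bool)
    record(0, active)
    for step in range(1, n_steps + 1):
        u, v = field_spec.velocity_cm_s(lat)
        dlat = v * dt_s / 1e2 / METERS_PER_DEG_LAT
        coslat = np.cos(np.radians(np.clip(lat, -85.0, 85.0)))
        dlon = u * dt_s / 1e2 / (METERS_PER_DEG_LAT * coslat)
        if field_spec.diffusion_sigma > 0:
            noise_km = rng.normal(0.0, field_spec.diffusion_sigma, size=(2, n_drifters))
            dlat = dlat + noise_km[0] * 1000.0 / METERS_PER_DEG_LAT
            dlon = dlon + noise_km[1] * 1000.0 / (METERS_PER_DEG_LAT * coslat)
        lat = np.clip(lat + dlat, -85.0, 85.0)
        lon = lon + dlon
        # wrap only out-of-range longitudes to keep in-range values exact
        out = (lon < -180.0) | (lon >= 180.0)
        if out.any():
            lon = np.where(out, ((lon + 180.0) % 360.0) - 180.0, lon)
        active = step <= max_steps
        if not active.any():
            break
        record(step, active)

    out = pd.DataFrame(
        {
            "drifter_id": np.concatenate(rec_id),
            "time": times[np.concatenate(rec_t)],
            "lat": np.concatenate(rec_lat),
            "lon": np.concatenate(rec_lon),
            "drogued": True,
        }
    )
    return out.sort_values(["drifter_id", "time"], kind="stable").reset_index(drop=True)
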