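"""Drifter-derived transport matrix and tracer advection.

Drifter trajectories are partitioned into non-overlapping windows of
``dt`` days; counts of window start -> end cell transitions on a regular
lat/lon grid, row-normalized, give a row-stochastic transition matrix.
Repeated application advects a virtual tracer whose accumulation mirrors
surface convergence; tracer is averaged over a longitudinal window when
read out at station positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import haversine_m

__all__ = [
    "GridSpec",
    "TransportMatrix",
    "TracerState",
    "build_transport_matrix",
    "advect",
    "mean_velocity_field",
    "station_tracer",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid; default 0.5 deg cells."""

    dx: float = 0.5
    dy: float = 0.5
    lat_bounds: tuple[float, float] = (-80.0, 80.0)
    lon_bounds: tuple[float, float] = (-180.0, 180.0)

    def __post_init__(self):
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx and dy must be positive")
        if self.lat_bounds[0] >= self.lat_bounds[1] or self.lon_bounds[0] >= self.lon_bounds[1]:
            raise ValueError("bounds must be ordered (min, max)")

    @property
    def nx(self) -> int:
        return int(np.ceil((self.lon_bounds[1] - self.lon_bounds[0]) / self.dx))

    @property
    def ny(self) -> int:
        return int(np.ceil((self.lat_bounds[1] - self.lat_bounds[0]) / self.dy))

    def cell_of(self, lat, lon):
        """Flat cell index; -1 for positions outside the bounds."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        iy = np.floor((lat - self.lat_bounds[0]) / self.dy).astype(int)
        ix = np.floor((lon - self.lon_bounds[0]) / self.dx).astype(int)
        ok = (iy >= 0) & (iy < self.ny) & (ix >= 0) & (ix < self.nx)
        return np.where(ok, iy * self.nx + ix, -1)

    def cell_center(self, flat):
        iy, ix = np.divmod(np.asarray(flat), self.nx)
        return (
            self.lat_bounds[0] + (iy + 0.5) * self.dy,
            self.lon_bounds[0] + (ix + 0.5) * self.dx,
        )


@dataclass
class TransportMatrix:
    """Row-stochastic cell-to-cell transition probabilities.

    ``cells`` lists the flat grid ids forming the state space; rows with
    no observed subtrajectory are absorbing (P_ii = 1).
    """

    p: np.ndarray
    cells: np.ndarray
    grid: GridSpec
    dt_days: float
    n_obs: np.ndarray = field(default=None)

    def cell_pos(self, flat: int) -> int:
        pos = np.searchsorted(self.cells, flat)
        if pos >= self.cells.size or self.cells[pos] != flat:
            return -1
        return int(pos)


@dataclass
class TracerState:
    concentration: np.ndarray  # per cell of the matrix state space
    elapsed_days: float


def build_transport_matrix(
    trajectories: pd.DataFrame,
    grid: GridSpec,
    dt_days: float = 30.0,
    drogued_only: bool = True,
    report_interval_h: float = 6.0,
) -> TransportMatrix:
    """Count start/end cells of non-overlapping ``dt`` windows per drifter.

    Fixes must be time-sorted per drifter at a regular reporting
    interval. Transitions with either endpoint off the grid are dropped.
    """
    traj = trajectories
    if drogued_only and "drogued" in traj.columns:
        traj = traj[traj["drogued"].astype(bool)]
    steps_per_window = int(round(dt_days * 24.0 / report_interval_h))
    if steps_per_window < 1:
        raise ValueError("dt shorter than the reporting interval")

    starts, ends = [], []
    for _, g in traj.groupby("drifter_id", sort=True):
        lat = g["lat"].to_numpy(dtype=float)
        lon = g["lon"].to_numpy(dtype=float)
        anchors = np.arange(0, lat.size, steps_per_window)
        if anchors.size < 2:
            continue
        cells = grid.cell_of(lat[anchors], lon[anchors])
        starts.append(cells[:-1])
        ends.append(cells[1:])
    if not starts:
        raise ValueError("no trajectory long enough for a single dt window")
    s = np.concatenate(starts)
    e = np.concatenate(ends)
    ok = (s >= 0) & (e >= 0)
    s, e = s[ok], e[ok]
    if s.size == 0:
        raise ValueError("all subtrajectories fall outside the grid bounds")

    cells = np.unique(np.concatenate([s, e]))
    pos = {c: i for i, c in enumerate(cells)}
    n = cells.size
    counts = np.zeros((n, n))
    for a, b in zip(s, e):
        counts[pos[a], pos[b]] += 1
    rowsum = counts.sum(axis=1)
    p = np.where(rowsum[:, None] > 0, counts / np.maximum(rowsum[:, None], 1.0), 0.0)
    for i in np.nonzero(rowsum == 0)[0]:
        p[i, i] = 1.0
    return TransportMatrix(p=p, cells=cells, grid=grid, dt_days=dt_days, n_obs=rowsum)


def advect(
    tm: TransportMatrix,
    initial: np.ndarray | None = None,
    n_years: int = 5,
    steps_per_year: int = 12,
) -> list[TracerState]:
    """Advect tracer mass by repeated application of the transition matrix.

    One step covers ``tm.dt_days``; a simulated year is ``steps_per_year``
    steps. Returns states at time zero and each year boundary. Mass is
    conserved because every row sums to one.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    n = tm.cells.size
    if initial is None:
        v = np.full(n, 1.0 / n)
    else:
        v = np.asarray(initial, dtype=float).copy()
        if v.shape != (n,):
            raise ValueError(f"initial state must have shape ({n},)")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("initial mass must be finite and non-negative")
    states = [TracerState(v.copy(), 0.0)]
    for year in range(1, n_years + 1):
        for _ in range(steps_per_year):
            v = v @ tm.p
        states.append(TracerState(v.copy(), year * steps_per_year * tm.dt_days))
    return states


def mean_velocity_field(trajectories: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Mean absolute drifter speed (cm/s) per grid cell.

    Per consecutive fix pair: great-circle displacement over elapsed
    time, attributed to the segment's starting cell.
    """
    sums: dict[int, float] = {}
    nums: dict[int, int] = {}
    for _, g in trajectories.groupby("drifter_id", sort=True):
        if len(g) < 2:
            continue
        lat = g["lat"].to_numpy(dtype=float)
        lon = g["lon"].to_numpy(dtype=float)
        t = pd.to_datetime(g["time"]).to_numpy()
        dt_s = (t[1:] - t[:-1]) / np.timedelta64(1, "s")
        dist = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
        speed = np.where(dt_s > 0, dist / np.maximum(dt_s, 1.0) * 100.0, 0.0)
        cell = grid.cell_of(lat[:-1], lon[:-1])
        for c, v in zip(cell, speed):
            if c < 0:
                continue
            sums[c] = sums.get(c, 0.0) + float(v)
            nums[c] = nums.get(c, 0) + 1
    rows = []
    for c in sorted(sums):
        lat_c, lon_c = grid.cell_center(c)
        rows.append({"cell": c, "lat": float(lat_c), "lon": float(lon_c),
                     "speed_cm_s": sums[c] / nums[c]})
    return pd.DataFrame(rows)


def station_tracer(
    tm: TransportMatrix,
    state: TracerState,
    stations: pd.DataFrame,
    n_lon_cells: int = 10,
) -> pd.Series:
    """Tracer concentration at station positions.

    For each station: the mean over ``n_lon_cells`` longitudinal cells
    centered on the station's cell, along the station's latitude row
    (cells in the window but outside the state space hold zero tracer;
    windows are clipped at the grid edge).
    """
    grid = tm.grid
    conc = np.zeros(grid.ny * grid.nx)
    conc[tm.cells] = state.concentration
    values = {}
    half = n_lon_cells // 2
    for sid, row in stations.iterrows():
        flat = int(grid.cell_of(row["lat"], row["lon"]))
        if flat < 0:
            raise ValueError(f"station {sid!r} lies outside the grid bounds")
        iy, ix = divmod(flat, grid.nx)
        lo = max(0, ix - half)
        hi = min(grid.nx, ix + (n_lon_cells - half))
        window = conc[iy * grid.nx + lo: iy * grid.nx + hi]
        values[sid] = float(window.mean())
    return pd.Series(values, name="tracer")
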