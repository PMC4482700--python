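"""Lagrangian particle simulation and coastal connectivity analysis.

Passive particles emulating drifting larvae are released daily from each
coastal cell through the spawning season, advected through daily surface
velocity fields with bilinear spatial interpolation (fields held
piecewise-constant within each calendar day), and tracked every
``step_hours`` (default 2 h, i.e. 12 steps/day) for the pelagic larval
duration (PLD).  A connectivity matrix then records, for each release
cell *i* and coastal cell *j*, the mean fraction of simulated steps that
particles from *i* spent inside *j*:

    C[i][j] = (steps of particles from i spent in j)
              / (n_particles_i * pld_days * steps_per_day)

so the diagonal measures larval retention and row sums are at most 1
(equal to 1 only when every step of every particle lies on the coastal
strip).  Annual matrices are averaged element-wise; matrices for
contrasting PLDs are compared with a Mantel test over all off-diagonal
cells; stepping-stone reach and dispersal barriers are read off the
thresholded directed connectivity graph.

Numerical conventions: forward-Euler advection by default (a classical
RK4 update is available via ``integrator="rk4"`` for convergence
checks); 111,320 m per degree latitude and that value times cos(lat) per
degree longitude; a step that would land on a land cell is cancelled and
the particle holds position for that step; a particle leaving the grid
bounds stops accruing steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gridio import CoastalCellIndex, GridSpec, VelocityFieldSeries
from .stats_core import PermutationTestResult, mantel_test
from .synthdata import METERS_PER_DEGREE

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class LPSConfig:
    """Simulation settings (defaults follow the study design)."""

    pld_days: int = 30
    step_hours: int = 2
    spawning_months: tuple[int, ...] = (5, 6, 7, 10, 11, 12, 1)
    years: tuple[int, ...] = (2008, 2009, 2010, 2011, 2012)
    particles_per_release: int = 1
    barrier_threshold: float = 0.05
    integrator: str = "euler"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.pld_days * 24) % self.step_hours != 0:
            raise ValueError("pld_days*24 must be divisible by step_hours")
        if not set(self.spawning_months) <= set(range(1, 13)):
            raise ValueError("spawning months must be calendar months 1..12")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError("integrator must be 'euler' or 'rk4'")

    @property
    def steps_per_day(self) -> int:
        return 24 // self.step_hours

    @property
    def n_steps(self) -> int:
        return self.pld_days * self.steps_per_day


@dataclass
class Trajectory:
    """One particle's 2-hourly track.

    ``positions`` holds (lon, lat) at release and after every completed
    step; if the particle exits the domain the track is truncated there
    and ``exit_step`` records the step at which it left.
    """

    cell_id: int
    release_date: pd.Timestamp
    positions: np.ndarray
    exit_step: int = -1  # -1 = stayed in the domain for the whole PLD

    @property
    def exited(self) -> bool:
        return self.exit_step >= 0


@dataclass
class ConnectivityMatrix:
    """Step-fraction connectivity between coastal cells."""

    cell_ids: np.ndarray
    values: np.ndarray
    pld_days: int
    years: tuple[int, ...] = ()
    n_particles: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.cell_ids)
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square over the cell ids")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("connectivity entries must lie in [0, 1]")
        if (self.values.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("connectivity row sums exceed 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.cell_ids)

    @property
    def retention(self) -> np.ndarray:
        return np.diag(self.values)


# ---------------------------------------------------------------------------
# release schedule
# ---------------------------------------------------------------------------

def build_release_schedule(config: LPSConfig, coastal: CoastalCellIndex) -> pd.DataFrame:
    """One release per coastal cell per spawning-season day.

    A January release is attributed to the simulation year containing
    that January (so each simulation year is the plain calendar year
    filtered to the spawning months).
    """
    rows = []
    if not config.years or not config.spawning_months:
        import logging
        logging.getLogger(__name__).warning("empty years or spawning months: no releases")
    for year in config.years:
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        days = days[days.month.isin(config.spawning_months)]
        for date in days:
            for cell in range(len(coastal)):
                for _ in range(config.particles_per_release):
                    rows.append((cell, date, year))
    return pd.DataFrame(rows, columns=["cell_id", "date", "year"])


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _bilinear(field: np.ndarray, grid: GridSpec, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Bilinear interpolation from cell-center values.

    Missing (NaN) neighbours contribute nothing and the remaining
    weights are renormalised; with all four neighbours missing the
    result is 0 (a particle surrounded by land feels no flow).  Beyond
    the outermost cell centers the field continues constant (indices
    clamped), exactness on linear fields holds in the interior.
    """
    fx = (lon - (grid.lon_min + grid.cell_size / 2)) / grid.cell_size
    fy = (lat - (grid.lat_min + grid.cell_size / 2)) / grid.cell_size
    x0 = np.clip(np.floor(fx).astype(int), 0, grid.n_lon - 1)
    y0 = np.clip(np.floor(fy).astype(int), 0, grid.n_lat - 1)
    x1 = np.clip(x0 + 1, 0, grid.n_lon - 1)
    y1 = np.clip(y0 + 1, 0, grid.n_lat - 1)
    tx = np.clip(fx - x0, 0.0, 1.0)
    ty = np.clip(fy - y0, 0.0, 1.0)

    total = np.zeros(lon.shape)
    weight = np.zeros(lon.shape)
    for (yy, xx, w) in (
        (y0, x0, (1 - tx) * (1 - ty)),
        (y0, x1, tx * (1 - ty)),
        (y1, x0, (1 - tx) * ty),
        (y1, x1, tx * ty),
    ):
        vals = field[yy, xx]
        ok = np.isfinite(vals)
        total = total + np.where(ok, w * np.where(ok, vals, 0.0), 0.0)
        weight = weight + np.where(ok, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(weight > 0, total / np.maximum(weight, 1e-300), 0.0)
    return out


def interp_velocity(series: VelocityFieldSeries, lon, lat, date) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) at the given positions on the given calendar day."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    k = series.day_index(date)
    u = _bilinear(series.u[k], series.grid, lon, lat)
    v = _bilinear(series.v[k], series.grid, lon, lat)
    return u, v


# ---------------------------------------------------------------------------
# advection
# ---------------------------------------------------------------------------

def _velocity_at(series: VelocityFieldSeries, day_idx: int, lon, lat):
    u = _bilinear(series.u[day_idx], series.grid, lon, lat)
    v = _bilinear(series.v[day_idx], series.grid, lon, lat)
    return u, v


def _step_displacement(series: VelocityFieldSeries, day_idx: int,
                       lon: np.ndarray, lat: np.ndarray, dt: float,
                       integrator: str) -> tuple[np.ndarray, np.ndarray]:
    def tendency(lo, la):
        u, v = _velocity_at(series, day_idx, lo, la)
        dlon = u * 1.0 / (METERS_PER_DEGREE * np.cos(np.radians(la)))
        dlat = v * 1.0 / METERS_PER_DEGREE
        return dlon, dlat

    if integrator == "euler":
        dlon, dlat = tendency(lon, lat)
        return dlon * dt, dlat * dt
    # RK4 with the day's (time-frozen) field
    k1 = tendency(lon, lat)
    k2 = tendency(lon + 0.5 * dt * k1[0], lat + 0.5 * dt * k1[1])
    k3 = tendency(lon + 0.5 * dt * k2[0], lat + 0.5 * dt * k2[1])
    k4 = tendency(lon + dt * k3[0], lat + dt * k3[1])
    dlon = dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    dlat = dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return dlon, dlat


def advect_batch(series: VelocityFieldSeries, lon0, lat0, release_date,
                 config: LPSConfig) -> tuple[np.ndarray, np.ndarray]:
    """Advect many particles released at the same instant.

    Returns ``(positions, exit_step)`` where positions has shape
    ``(n, n_steps+1, 2)`` (lon, lat; NaN after a particle exits) and
    ``exit_step[i]`` is the 1-based step at which particle *i* left the
    grid bounds, or -1.  If the velocity series ends before the PLD does,
    the remaining steps are treated like a domain exit in time: particles
    freeze and stop accruing steps.
    """
    lon = np.array(lon0, dtype=float, copy=True)
    lat = np.array(lat0, dtype=float, copy=True)
    n = lon.size
    grid = series.grid
    land = series.land_mask
    release = pd.Timestamp(release_date)
    dt = config.step_hours * SECONDS_PER_HOUR

    positions = np.full((n, config.n_steps + 1, 2), np.nan)
    positions[:, 0, 0] = lon
    positions[:, 0, 1] = lat
    exit_step = np.full(n, -1, dtype=int)
    active = np.ones(n, dtype=bool)

    last_day = series.dates[-1]
    for step in range(1, config.n_steps + 1):
        t = release + pd.Timedelta(hours=(step - 1) * config.step_hours)
        day = t.normalize()
        if day > last_day:
            exit_step[active] = step
            break
        day_idx = series.day_index(day)
        if not active.any():
            break
        dlon, dlat = _step_displacement(series, day_idx, lon[active], lat[active],
                                        dt, config.integrator)
        new_lon = lon[active] + dlon
        new_lat = lat[active] + dlat

        inside = grid.contains(new_lon, new_lat)
        ix, iy = grid.cell_index(new_lon, new_lat)
        on_land = np.zeros(new_lon.shape, dtype=bool)
        on_land[inside] = land[iy[inside], ix[inside]]

        move = inside & ~on_land
        hold = inside & on_land
        out = ~inside

        idx_active = np.flatnonzero(active)
        lon[idx_active[move]] = new_lon[move]
        lat[idx_active[move]] = new_lat[move]
        # held particles keep lon/lat unchanged
        exit_step[idx_active[out]] = step
        active[idx_active[out]] = False

        still = np.flatnonzero(active)
        positions[still, step, 0] = lon[still]
        positions[still, step, 1] = lat[still]
    return positions, exit_step


def advect_particle(series: VelocityFieldSeries, lon: float, lat: float,
                    release_date, config: LPSConfig, cell_id: int = -1) -> Trajectory:
    """Advect a single particle; errors if released on land."""
    ix, iy = series.grid.cell_index(lon, lat)
    if ix < 0:
        raise ValueError("release position outside the grid")
    if series.land_mask[int(iy), int(ix)]:
        raise ValueError(f"release position ({lon}, {lat}) is on land")
    pos, exit_step = advect_batch(series, [lon], [lat], release_date, config)
    track = pos[0]
    es = int(exit_step[0])
    if es >= 0:
        track = track[:es]
    return Trajectory(cell_id=cell_id, release_date=pd.Timestamp(release_date),
                      positions=track, exit_step=es)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

@dataclass
class YearRun:
    """Aggregated step-occupancy for one simulation year.

    ``step_counts[i, j]`` is the total number of particle-steps spent by
    particles released from coastal cell *i* inside coastal cell *j*;
    ``n_released[i]`` counts particles released from *i*.
    """

    year: int
    step_counts: np.ndarray
    n_released: np.ndarray


def _coastal_id_grid(coastal: CoastalCellIndex) -> np.ndarray:
    id_grid = np.full(coastal.grid.shape, -1, dtype=int)
    for k, (ix, iy) in enumerate(coastal.cells):
        id_grid[iy, ix] = k
    return id_grid


def run_lps(config: LPSConfig, series: VelocityFieldSeries,
            coastal: CoastalCellIndex, keep_trajectories: bool = False):
    """Run the full release schedule, aggregating occupancy per year.

    Returns a list of :class:`YearRun` (and, when ``keep_trajectories``,
    the flat trajectory list as a second element).  Deterministic for a
    given (config, series, coastline) — randomness only enters upstream,
    through velocity-field noise.
    """
    centers = coastal.centers()
    land = series.land_mask
    for k, (ix, iy) in enumerate(coastal.cells):
        if land[iy, ix]:
            raise ValueError(f"coastal cell {k} lies on land in the velocity series")
    schedule = build_release_schedule(config, coastal)
    id_grid = _coastal_id_grid(coastal)
    n_cells = len(coastal)
    runs: dict[int, YearRun] = {}
    trajectories: list[Trajectory] = []

    for (year, date), grp in schedule.groupby(["year", "date"], sort=True):
        cells = grp["cell_id"].to_numpy()
        lon0 = centers[cells, 0]
        lat0 = centers[cells, 1]
        positions, exit_step = advect_batch(series, lon0, lat0, date, config)
        if year not in runs:
            runs[year] = YearRun(year=int(year),
                                 step_counts=np.zeros((n_cells, n_cells)),
                                 n_released=np.zeros(n_cells))
        rec = runs[year]
        np.add.at(rec.n_released, cells, 1)
        # occupancy of steps 1..n (release position itself is not a step)
        steps = positions[:, 1:, :]
        ix, iy = series.grid.cell_index(steps[..., 0], steps[..., 1])
        ids = np.where(ix >= 0, id_grid[iy, ix], -1)
        for p in range(len(cells)):
            occupied = ids[p][ids[p] >= 0]
            if occupied.size:
                np.add.at(rec.step_counts[cells[p]], occupied, 1)
        if keep_trajectories:
            for p in range(len(cells)):
                es = int(exit_step[p])
                track = positions[p] if es < 0 else positions[p, :es]
                trajectories.append(Trajectory(int(cells[p]), pd.Timestamp(date),
                                               track, es))
    out = [runs[y] for y in sorted(runs)]
    return (out, trajectories) if keep_trajectories else out


def connectivity_matrix(run: YearRun, coastal: CoastalCellIndex,
                        config: LPSConfig) -> ConnectivityMatrix:
    """Normalise a year's occupancy counts into step-fraction probabilities."""
    denom = run.n_released * config.n_steps
    values = np.zeros_like(run.step_counts)
    released = denom > 0
    values[released] = run.step_counts[released] / denom[released, None]
    return ConnectivityMatrix(cell_ids=np.arange(len(coastal)), values=values,
                              pld_days=config.pld_days, years=(run.year,),
                              n_particles=int(run.n_released.sum()))


def connectivity_from_trajectories(trajectories: Sequence[Trajectory],
                                   coastal: CoastalCellIndex,
                                   config: LPSConfig) -> ConnectivityMatrix:
    """Connectivity straight from explicit trajectories (small runs/tests)."""
    n = len(coastal)
    counts = np.zeros((n, n))
    released = np.zeros(n)
    id_grid = _coastal_id_grid(coastal)
    for tr in trajectories:
        if not 0 <= tr.cell_id < n:
            raise ValueError(f"trajectory references unknown coastal cell {tr.cell_id}")
        released[tr.cell_id] += 1
        pos = tr.positions[1:]
        if pos.size == 0:
            continue
        ix, iy = coastal.grid.cell_index(pos[:, 0], pos[:, 1])
        ids = np.where(ix >= 0, id_grid[iy, ix], -1)
        ids = ids[ids >= 0]
        if ids.size:
            np.add.at(counts[tr.cell_id], ids, 1)
    denom = released * config.n_steps
    values = np.zeros_like(counts)
    ok = denom > 0
    values[ok] = counts[ok] / denom[ok, None]
    return ConnectivityMatrix(cell_ids=np.arange(n), values=values,
                              pld_days=config.pld_days,
                              n_particles=int(released.sum()))


def average_annual(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of annual matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape or not np.array_equal(m.cell_ids, first.cell_ids):
            raise ValueError("annual matrices must share shape and cell ids")
    mean = np.mean([m.values for m in matrices], axis=0)
    years = tuple(sorted({y for m in matrices for y in m.years}))
    return ConnectivityMatrix(cell_ids=first.cell_ids.copy(), values=mean,
                              pld_days=first.pld_days, years=years,
                              n_particles=sum(m.n_particles for m in matrices))


def compare_pld(c_a: ConnectivityMatrix, c_b: ConnectivityMatrix,
                n_perm: int = 9999, seed: int | None = 0) -> PermutationTestResult:
    """Mantel correlation between connectivity matrices of two PLDs."""
    if not np.array_equal(c_a.cell_ids, c_b.cell_ids):
        raise ValueError("matrices cover different coastal cell sets")
    return mantel_test(c_a.values, c_b.values, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# graph analyses
# ---------------------------------------------------------------------------

def _edges(values: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    n = values.shape[0]
    adj = (values > threshold) & ~np.eye(n, dtype=bool)
    idx = np.arange(n)
    if direction == "up":
        adj &= idx[None, :] > idx[:, None]
    elif direction == "down":
        adj &= idx[None, :] < idx[:, None]
    elif direction != "both":
        raise ValueError("direction must be 'up', 'down' or 'both'")
    return adj


def stepping_stone_reach(c: ConnectivityMatrix, sources: Iterable[int],
                         threshold: float = 0.05, direction: str = "both") -> set[int]:
    """Transitive closure of above-threshold dispersal from source cells.

    Models a year-to-year stepping-stone scenario: an edge i -> j exists
    when C[i][j] > threshold (strictly), optionally restricted to
    increasing ("up") or decreasing ("down") coastal ids.  Sources are
    always part of the reachable set.
    """
    n = c.values.shape[0]
    sources = list(sources)
    for s in sources:
        if not 0 <= s < n:
            raise ValueError(f"unknown source cell {s}")
    adj = _edges(c.values, threshold, direction)
    reached = set(sources)
    frontier = list(sources)
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(adj[i]):
            if j not in reached:
                reached.add(int(j))
                frontier.append(int(j))
    return reached


def detect_barriers(c: ConnectivityMatrix, coastal: CoastalCellIndex | None = None,
                    threshold: float = 0.05, direction: str = "up") -> list[int]:
    """Cut points of the thresholded connectivity graph along the coast.

    A barrier is reported between adjacent coastal cells (k, k+1) when no
    cell with id <= k connects, above ``threshold``, to any cell with id
    >= k+1 ("up" direction; "down" swaps the roles).  Returns the list of
    k values (the cell on the upstream side of each cut).
    """
    v = c.values
    n = v.shape[0]
    if direction == "down":
        v = v[::-1, ::-1]
    elif direction != "up":
        raise ValueError("direction must be 'up' or 'down'")
    nodiag = v * (~np.eye(n, dtype=bool))
    # best[k] = max over i<=k, j>=k+1 of C[i][j]
    suffix = np.maximum.accumulate(nodiag[:, ::-1], axis=1)[:, ::-1]  # suffix max over j
    cuts = []
    for k in range(n - 1):
        best = suffix[: k + 1, k + 1].max()
        if best <= threshold:
            cuts.append(k if direction == "up" else n - 2 - k)
    return sorted(cuts)
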