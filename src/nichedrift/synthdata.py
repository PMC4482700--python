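"""Synthetic coastlines, currents, predictors and occurrence surveys.

Every pipeline stage is exercised against data with known ground truth:

* an idealised coastline (straight or L-shaped) with land strictly on one
  side, gridded at the working resolution;
* daily velocity fields containing a coast-parallel jet that deflects
  offshore at a prescribed front latitude — the mechanism behind the
  Benguela-type dispersal barrier — plus an optional inshore
  counter-current band flowing against the jet (Agulhas-type nearshore
  return flow);
* closed-form flows (uniform, solid-body rotation, double gyre) for
  testing the particle integrator against analytic trajectories;
* environmental predictor rasters built from latitudinal gradients plus
  seeded noise;
* presence/absence surveys drawn from a known thermal-envelope niche.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridio import (
    CoastalCellIndex,
    GridSpec,
    OccurrenceSet,
    Raster2D,
    VelocityFieldSeries,
    make_occurrences,
)

#: meters per degree of latitude; longitude scales by cos(lat).
#: Shared with the particle-tracking module so generated speeds and
#: advected displacements use the same metric.
METERS_PER_DEGREE = 111_320.0


@dataclass(frozen=True)
class NicheTruth:
    """A thermal-envelope niche with smooth logistic edges.

    Suitability is ~1 for temperatures inside ``[t_min, t_max]`` and
    decays over an edge width ``w`` (°C) outside it; ``p_detect`` thins
    presences to emulate imperfect survey detection.
    """

    t_min: float = 15.0
    t_max: float = 22.0
    w: float = 0.1
    p_detect: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be below t_max")
        if self.w <= 0:
            raise ValueError("edge width w must be positive")
        if not 0 < self.p_detect <= 1:
            raise ValueError("p_detect must be in (0, 1]")

    def suitability(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo = 1.0 / (1.0 + np.exp(-(t - self.t_min) / self.w))
        hi = 1.0 / (1.0 + np.exp(-(self.t_max - t) / self.w))
        return lo * hi


# ---------------------------------------------------------------------------
# coastline
# ---------------------------------------------------------------------------

def gen_coastline(n_cells: int, orientation: str, grid: GridSpec,
                  land_width: int = 2) -> tuple[CoastalCellIndex, Raster2D]:
    """Build an idealised coastline and its land mask.

    ``orientation`` is one of:

    * ``"meridional"`` — land strip on the eastern edge, coast running
      south to north; coastal ids increase northward.
    * ``"zonal"`` — land strip on the southern edge, ids increase eastward.
    * ``"L"`` — land fills the south-east corner block; the coastal path
      runs west-to-east along the southern shore, turns at the corner and
      continues northward, preserving adjacency.

    Returns the ordered coastal index and a land raster (1 = land, 0 = sea).
    """
    land = np.zeros(grid.shape, dtype=float)
    cells: list[tuple[int, int]] = []
    if n_cells < 2:
        raise ValueError("need at least 2 coastal cells")

    if orientation == "meridional":
        if n_cells > grid.n_lat:
            raise ValueError("n_cells exceeds grid extent in latitude")
        coast_ix = grid.n_lon - land_width - 1
        if coast_ix < 0:
            raise ValueError("grid too narrow for the requested land strip")
        land[:, coast_ix + 1:] = 1.0
        cells = [(coast_ix, iy) for iy in range(n_cells)]
    elif orientation == "zonal":
        if n_cells > grid.n_lon:
            raise ValueError("n_cells exceeds grid extent in longitude")
        coast_iy = land_width
        if coast_iy >= grid.n_lat:
            raise ValueError("grid too short for the requested land strip")
        land[:coast_iy, :] = 1.0
        cells = [(ix, coast_iy) for ix in range(n_cells)]
    elif orientation == "L":
        # south-east land block; path: along the south shore, corner, north
        n_zonal = n_cells // 2
        n_merid = n_cells - n_zonal
        coast_ix = grid.n_lon - land_width - 1
        coast_iy = land_width
        if coast_ix < n_zonal or coast_iy >= grid.n_lat or n_merid + coast_iy > grid.n_lat:
            raise ValueError("n_cells exceeds grid extent for an L-shaped coast")
        land[:coast_iy, coast_ix - n_zonal + 1:] = 1.0
        land[coast_iy: coast_iy + n_merid, coast_ix + 1:] = 1.0
        cells = [(coast_ix - n_zonal + k, coast_iy) for k in range(n_zonal)]
        cells += [(coast_ix, coast_iy + k) for k in range(n_merid)]
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    index = CoastalCellIndex(grid, cells)
    return index, Raster2D(grid, land, name="land", units="mask")


# ---------------------------------------------------------------------------
# velocity fields
# ---------------------------------------------------------------------------

def _daily_index(dates) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(dates)
    if len(idx) == 0:
        raise ValueError("dates must be nonempty")
    return idx


def gen_velocity_jet(
    grid: GridSpec,
    dates,
    jet_speed: float,
    jet_direction: str = "north",
    front_lat: float | None = None,
    offshore_deflection: float = 0.0,
    counter_current_speed: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    land: Raster2D | None = None,
    nearshore_factor: float = 0.15,
    core_distance: int = 2,
) -> VelocityFieldSeries:
    """Coast-parallel jet with an offshore-deflection front.

    The coast is assumed meridional with land on the eastern edge (pass
    the land raster from :func:`gen_coastline`).  South of ``front_lat``
    the alongshore (meridional) velocity is ``jet_speed`` in the jet core
    (cells at least ``core_distance`` columns off the coast), tapering
    linearly toward the coast down to ``nearshore_factor * jet_speed`` in
    the coastal column.  If ``counter_current_speed > 0`` the coastal
    column instead carries an opposing inshore flow of that speed.
    Poleward of ``front_lat`` the flow rotates offshore: meridional flow
    vanishes and a westward (seaward) component of magnitude
    ``offshore_deflection`` appears.  Per-day, per-cell Gaussian noise of
    sd ``noise_sd`` is added before land masking.
    """
    if jet_speed < 0:
        raise ValueError("jet_speed must be non-negative")
    idx = _daily_index(dates)
    if front_lat is not None and not (grid.lat_min <= front_lat <= grid.lat_max):
        raise ValueError("front_lat outside grid latitude bounds")
    sign = {"north": 1.0, "south": -1.0}.get(jet_direction)
    if sign is None:
        raise ValueError("jet_direction must be 'north' or 'south'")

    land_mask = np.zeros(grid.shape, dtype=bool)
    coast_ix = grid.n_lon - 1
    if land is not None:
        land_mask = land.values > 0
        sea_cols = np.where(~land_mask.all(axis=0))[0]
        coast_ix = int(sea_cols.max()) if sea_cols.size else 0

    # offshore distance (in columns) from the coastal column; land cells ignored
    dist = coast_ix - np.arange(grid.n_lon)  # 0 at the coast, grows seaward
    taper = nearshore_factor + (1.0 - nearshore_factor) * np.clip(
        dist / max(core_distance, 1), 0.0, 1.0)
    v_row = sign * jet_speed * taper
    if counter_current_speed > 0:
        v_row = np.where(dist == 0, -sign * counter_current_speed, v_row)
    v0 = np.tile(v_row, (grid.n_lat, 1))
    u0 = np.zeros(grid.shape)

    if front_lat is not None:
        # the front always truncates the northern end of the domain: there the
        # alongshore flow dies and an offshore (westward) component appears,
        # ejecting both jet-borne and counter-current-borne particles
        beyond = grid.lat_centers() >= front_lat
        v0[beyond, :] = 0.0
        u0[beyond, :] = -abs(offshore_deflection)  # seaward = westward (land east)

    rng = np.random.default_rng(seed)
    nt = len(idx)
    u = np.repeat(u0[None, :, :], nt, axis=0)
    v = np.repeat(v0[None, :, :], nt, axis=0)
    if noise_sd > 0:
        u = u + rng.normal(0.0, noise_sd, size=u.shape)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    u[:, land_mask] = np.nan
    v[:, land_mask] = np.nan
    return VelocityFieldSeries(grid, idx, u, v)


def gen_analytic_flow(kind: str, params: dict, grid: GridSpec, dates) -> VelocityFieldSeries:
    """Closed-form flows sampled exactly at cell centers.

    kinds:
      ``uniform``        — params u, v (m/s)
      ``solid_rotation`` — params omega (rad/s), center=(lon, lat); the
                           velocity is omega x r with r measured in meters
                           via the package's degrees-to-meters convention
                           (local tangent plane around the center)
      ``double_gyre``    — params A (m/s), eps, period_days on the unit
                           domain mapped to the grid extent; normal flow
                           vanishes on the domain boundary
    """
    idx = _daily_index(dates)
    lonc, latc = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    nt = len(idx)

    if kind == "uniform":
        u0 = np.full(grid.shape, float(params.get("u", 0.0)))
        v0 = np.full(grid.shape, float(params.get("v", 0.0)))
        u = np.repeat(u0[None], nt, axis=0)
        v = np.repeat(v0[None], nt, axis=0)
    elif kind == "solid_rotation":
        omega = float(params["omega"])
        c_lon, c_lat = params.get("center", ((grid.lon_min + grid.lon_max) / 2,
                                             (grid.lat_min + grid.lat_max) / 2))
        x = (lonc - c_lon) * METERS_PER_DEGREE * np.cos(np.radians(c_lat))
        y = (latc - c_lat) * METERS_PER_DEGREE
        u0, v0 = -omega * y, omega * x
        u = np.repeat(u0[None], nt, axis=0)
        v = np.repeat(v0[None], nt, axis=0)
    elif kind == "double_gyre":
        A = float(params.get("A", 0.1))
        eps = float(params.get("eps", 0.25))
        period = float(params.get("period_days", 10.0))
        xs = (lonc - grid.lon_min) / (grid.lon_max - grid.lon_min) * 2.0  # [0, 2]
        ys = (latc - grid.lat_min) / (grid.lat_max - grid.lat_min)        # [0, 1]
        u = np.empty((nt,) + grid.shape)
        v = np.empty((nt,) + grid.shape)
        t_days = (idx - idx[0]).days.to_numpy(dtype=float)
        for k, t in enumerate(t_days):
            omega_t = 2 * np.pi * t / period
            a = eps * np.sin(omega_t)
            b = 1 - 2 * a
            f = a * xs**2 + b * xs
            dfdx = 2 * a * xs + b
            u[k] = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * ys)
            v[k] = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * ys) * dfdx
    else:
        raise ValueError(f"unknown analytic flow kind {kind!r}")
    return VelocityFieldSeries(grid, idx, u, v)


# ---------------------------------------------------------------------------
# environmental predictors
# ---------------------------------------------------------------------------

def gen_env_predictors(grid: GridSpec, gradients, noise_sd: float = 0.0,
                       seed: int = 0, intercepts=None, names=None,
                       units: str = "degC") -> list[Raster2D]:
    """Latitudinal-gradient predictor rasters with seeded noise.

    ``gradients[k]`` is the slope of predictor ``k`` in units per degree
    latitude; the value at a cell is ``intercept + slope * lat_center``
    plus independent Gaussian noise of sd ``noise_sd``.  Predictors built
    from the same gradient share their latent latitudinal structure, so
    any requested rank-correlation pattern can be induced by reusing or
    negating slopes.
    """
    gradients = list(np.atleast_1d(gradients).astype(float))
    n = len(gradients)
    intercepts = [0.0] * n if intercepts is None else list(np.atleast_1d(intercepts))
    names = [f"pred{k}" for k in range(n)] if names is None else list(names)
    rng = np.random.default_rng(seed)
    lat = grid.lat_centers()[:, None]
    out = []
    for k in range(n):
        vals = intercepts[k] + gradients[k] * lat * np.ones((1, grid.n_lon))
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=grid.shape)
        out.append(Raster2D(grid, vals, name=names[k], units=units))
    return out


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def gen_occurrences(
    truth: NicheTruth,
    predictor: Raster2D,
    n_presence: int,
    n_survey_absence: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    absence_mode: str = "outside",
    year: int = 2010,
) -> OccurrenceSet:
    """Draw a synthetic survey from a known thermal envelope.

    Presence cells are sampled without replacement from the predictor's
    valid cells with probability proportional to
    ``truth.suitability(T) * p_detect``; records are placed at cell
    centers, so the set is already gridded.  Survey absences are sampled
    uniformly from the remaining cells — restricted to cells outside the
    envelope (suitability < 0.5) when ``absence_mode="outside"``, or from
    any non-presence cell when ``"anywhere"``.  Range labels are assigned
    by region from ``ranges``: each label maps to either a latitude
    interval ``(lat_lo, lat_hi)`` or a box ``{"lon": (lo, hi), "lat":
    (lo, hi)}`` (either axis optional); the first matching label wins and
    points matching none get the first label.  Boxes make nested-niche
    scenarios possible — a geographically separate invaded region whose
    environmental conditions are a subset of the native ones.
    """
    rng = np.random.default_rng(seed)
    mask = predictor.mask
    iy, ix = np.nonzero(mask)
    temps = predictor.values[iy, ix]
    weights = truth.suitability(temps) * truth.p_detect
    suitable = weights > 1e-9
    if n_presence > suitable.sum():
        raise ValueError(
            f"requested {n_presence} presences but only {int(suitable.sum())} cells "
            "have non-zero suitability"
        )
    p = weights / weights.sum()
    chosen = rng.choice(len(temps), size=n_presence, replace=False, p=p)

    pool = np.setdiff1d(np.arange(len(temps)), chosen)
    if absence_mode == "outside":
        pool = pool[truth.suitability(temps[pool]) < 0.5]
    elif absence_mode != "anywhere":
        raise ValueError("absence_mode must be 'outside' or 'anywhere'")
    if n_survey_absence > len(pool):
        raise ValueError(
            f"requested {n_survey_absence} absences but only {len(pool)} eligible cells"
        )
    chosen_abs = rng.choice(pool, size=n_survey_absence, replace=False) if n_survey_absence else np.array([], dtype=int)

    def cells_to_lonlat(sel):
        lon = predictor.grid.lon_min + (ix[sel] + 0.5) * predictor.grid.cell_size
        lat = predictor.grid.lat_min + (iy[sel] + 0.5) * predictor.grid.cell_size
        return lon, lat

    lon_p, lat_p = cells_to_lonlat(chosen)
    lon_a, lat_a = cells_to_lonlat(chosen_abs)
    lon = np.concatenate([lon_p, lon_a])
    lat = np.concatenate([lat_p, lat_a])
    occ = np.concatenate([np.ones(n_presence, int), np.zeros(len(chosen_abs), int)])

    if ranges:
        labels = np.array([_range_label(lo_, la, ranges)
                           for lo_, la in zip(lon, lat)], dtype=object)
    else:
        labels = np.full(len(lat), "native", dtype=object)
    return make_occurrences(lon, lat, occ, range_label=labels, year=year)


def _range_label(lon: float, lat: float, ranges: dict) -> str:
    for label, spec in ranges.items():
        if isinstance(spec, dict):
            lon_ok = "lon" not in spec or spec["lon"][0] <= lon < spec["lon"][1]
            lat_ok = "lat" not in spec or spec["lat"][0] <= lat < spec["lat"][1]
            if lon_ok and lat_ok:
                return label
        else:
            lo, hi = spec
            if lo <= lat < hi:
                return label
    return next(iter(ranges))
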