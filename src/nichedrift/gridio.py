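"""Grid conventions, domain containers and file I/O.

Everything downstream (niche models, divergence tests, particle tracking)
shares one spatial convention defined here: a regular lon/lat grid whose
cell ``(i, j)`` spans the half-open intervals

    lon in [lon_min + i*cell_size, lon_min + (i+1)*cell_size)
    lat in [lat_min + j*cell_size, lat_min + (j+1)*cell_size)

with 0-based indices.  A point exactly on a cell's upper edge belongs to
the next cell.  Value arrays are stored ``[lat, lon]`` (row = latitude
band), matching the CF ordering used in the NetCDF carriers.

File carriers:

* occurrence records — CSV with columns ``year, source, Lon, Lat,
  Occurrence, range, reference`` (header names matched case-insensitively,
  any column order);
* rasters and daily velocity fields — CF-style NetCDF (classic format,
  written through :mod:`xarray`), velocity variables default to
  ``water_u`` / ``water_v``;
* connectivity matrices — CSV with coastal-cell ids as row/column labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: columns of the occurrence CSV schema, in canonical order
OCCURRENCE_COLUMNS = ("year", "source", "lon", "lat", "occurrence", "range", "reference")

#: header aliases accepted (lower-cased) for each canonical column
_HEADER_ALIASES = {
    "year": "year",
    "source": "source",
    "lon": "lon",
    "longitude": "lon",
    "lat": "lat",
    "latitude": "lat",
    "occurrence": "occurrence",
    "range": "range",
    "reference": "reference",
}

RANGE_LABELS = ("native", "non-native")


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with half-open, 0-based cells."""

    lon_min: float
    lat_min: float
    cell_size: float = 0.08
    n_lon: int = 1
    n_lat: int = 1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_lat, n_lon)``."""
        return (self.n_lat, self.n_lon)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (ix, iy) cell indices.  Points outside -> -1.

        The half-open convention is realised by ``floor``; a coordinate
        exactly on an upper cell edge falls into the next cell.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)  # False for NaN positions
        lon_safe = np.where(inside, lon, self.lon_min)
        lat_safe = np.where(inside, lat, self.lat_min)
        ix = np.floor((lon_safe - self.lon_min) / self.cell_size).astype(int)
        iy = np.floor((lat_safe - self.lat_min) / self.cell_size).astype(int)
        ix = np.where(inside, ix, -1)
        iy = np.where(inside, iy, -1)
        return ix, iy

    def cell_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            self.lon_min + (ix + 0.5) * self.cell_size,
            self.lat_min + (iy + 0.5) * self.cell_size,
        )


# ---------------------------------------------------------------------------
# raster
# ---------------------------------------------------------------------------

@dataclass
class Raster2D:
    """A single gridded field (environmental predictor, suitability map...).

    ``values`` has shape ``grid.shape = (n_lat, n_lon)``; missing cells are
    NaN, never silently zero.
    """

    grid: GridSpec
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a value."""
        return np.isfinite(self.values)

    def value_at(self, lon, lat) -> np.ndarray:
        """Cell value at each point; NaN outside the grid."""
        ix, iy = self.grid.cell_index(lon, lat)
        out = np.full(np.shape(ix), np.nan, dtype=float)
        ok = ix >= 0
        out[ok] = self.values[iy[ok], ix[ok]]
        return out

    def copy_with(self, values: np.ndarray, name: str | None = None,
                  units: str | None = None) -> "Raster2D":
        return Raster2D(self.grid, np.asarray(values, dtype=float),
                        self.name if name is None else name,
                        self.units if units is None else units)


# ---------------------------------------------------------------------------
# velocity fields
# ---------------------------------------------------------------------------

@dataclass
class VelocityFieldSeries:
    """Daily surface-current fields (u eastward, v northward, m/s).

    ``u`` and ``v`` have shape ``(n_days, n_lat, n_lon)`` and share the
    same missing mask (NaN = land).  ``dates`` are strictly increasing
    calendar days.
    """

    grid: GridSpec
    dates: pd.DatetimeIndex
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        expected = (len(self.dates),) + self.grid.shape
        if self.u.shape != expected or self.v.shape != expected:
            raise ValueError(
                f"u/v shapes {self.u.shape}/{self.v.shape} do not match {expected}"
            )
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[h]").astype(int)
            if not np.all(deltas == 24):
                raise ValueError("dates must be strictly increasing, daily")
        if not np.array_equal(np.isfinite(self.u), np.isfinite(self.v)):
            raise ValueError("u and v must share the same missing (land) mask")

    @property
    def land_mask(self) -> np.ndarray:
        """True where a cell is land (missing on every day)."""
        return ~np.isfinite(self.u).any(axis=0)

    def day_index(self, date) -> int:
        ts = pd.Timestamp(date).normalize()
        idx = self.dates.get_indexer([ts])
        if idx[0] < 0:
            raise KeyError(f"date {ts.date()} not covered by the series")
        return int(idx[0])


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

class OccurrenceSet:
    """Presence/absence records with range labels, optionally gridded.

    Backed by a DataFrame with the canonical columns
    ``year, source, lon, lat, occurrence, range, reference``.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy().reset_index(drop=True)
        missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing occurrence columns: {missing}")
        df["occurrence"] = df["occurrence"].astype(int)
        bad = ~df["occurrence"].isin((0, 1))
        if bad.any():
            raise ValueError(
                f"occurrence must be 0 or 1; found {sorted(df.loc[bad, 'occurrence'].unique())}"
            )
        df["lon"] = df["lon"].astype(float)
        df["lat"] = df["lat"].astype(float)
        self.records = df[list(OCCURRENCE_COLUMNS)]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OccurrenceSet):
            return NotImplemented
        return self.records.equals(other.records)

    @property
    def presences(self) -> pd.DataFrame:
        return self.records[self.records["occurrence"] == 1]

    @property
    def absences(self) -> pd.DataFrame:
        return self.records[self.records["occurrence"] == 0]

    def subset(self, mask) -> "OccurrenceSet":
        return OccurrenceSet(self.records[mask])


def make_occurrences(lon, lat, occurrence, range_label="native", year=2010,
                     source="synthetic", reference="") -> OccurrenceSet:
    """Convenience constructor broadcasting scalar metadata columns."""
    n = len(np.atleast_1d(lon))
    df = pd.DataFrame(
        {
            "year": np.broadcast_to(year, n).copy(),
            "source": np.broadcast_to(source, n).copy(),
            "lon": np.asarray(lon, dtype=float),
            "lat": np.asarray(lat, dtype=float),
            "occurrence": np.asarray(occurrence, dtype=int),
            "range": np.broadcast_to(range_label, n).copy(),
            "reference": np.broadcast_to(reference, n).copy(),
        }
    )
    return OccurrenceSet(df)


def grid_occurrences(raw: OccurrenceSet | pd.DataFrame, grid: GridSpec) -> OccurrenceSet:
    """Snap records to the grid, one record per cell.

    Duplicate records in one cell collapse to a single one (the first by
    input order).  A cell holding both a presence and an absence resolves
    to presence: survey absences are kept apart from the presence-only
    modelling and only a presence unambiguously establishes occupancy.
    Records outside the grid bounds are dropped with a logged count.
    """
    df = raw.records if isinstance(raw, OccurrenceSet) else pd.DataFrame(raw)
    if not np.isfinite(df["lon"]).all() or not np.isfinite(df["lat"]).all():
        raise ValueError("records must have finite lon/lat")
    ix, iy = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    inside = ix >= 0
    n_rejected = int((~inside).sum())
    if n_rejected:
        logger.warning("grid_occurrences: rejected %d record(s) outside grid bounds", n_rejected)
    df = df[inside].copy()
    df["_ix"], df["_iy"] = ix[inside], iy[inside]
    # presence wins within a cell; stable order otherwise
    df = df.sort_values("occurrence", ascending=False, kind="stable")
    df = df.drop_duplicates(subset=["_ix", "_iy"], keep="first")
    df = df.sort_index().drop(columns=["_ix", "_iy"])
    return OccurrenceSet(df)


# ---------------------------------------------------------------------------
# coastal cells
# ---------------------------------------------------------------------------

@dataclass
class CoastalCellIndex:
    """Ordered coastal cells forming a path along the coastline.

    ``cells[k]`` is the ``(ix, iy)`` grid cell of coastal id ``k``;
    consecutive ids are geographic neighbours.
    """

    grid: GridSpec
    cells: list[tuple[int, int]]
    _lookup: dict[tuple[int, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._lookup = {}
        for k, (ix, iy) in enumerate(self.cells):
            if (ix, iy) in self._lookup:
                raise ValueError(f"cell {(ix, iy)} appears twice in the coastal index")
            self._lookup[(ix, iy)] = k
        for (x0, y0), (x1, y1) in zip(self.cells[:-1], self.cells[1:]):
            if abs(x0 - x1) + abs(y0 - y1) != 1:
                raise ValueError("coastal cells must form a 4-connected path")

    def __len__(self) -> int:
        return len(self.cells)

    def centers(self) -> np.ndarray:
        """(n, 2) array of (lon, lat) cell centers, in coastal order."""
        return np.array([self.grid.cell_center(ix, iy) for ix, iy in self.cells])

    def id_of(self, ix: int, iy: int) -> int | None:
        return self._lookup.get((int(ix), int(iy)))

    def ids_at(self, lon, lat) -> np.ndarray:
        """Coastal id under each point, -1 when off the coastal strip."""
        ix, iy = self.grid.cell_index(lon, lat)
        flat = np.full(np.shape(ix), -1, dtype=int)
        it = np.nditer(ix, flags=["multi_index"])
        for _ in it:
            m = it.multi_index
            if ix[m] >= 0:
                k = self._lookup.get((int(ix[m]), int(iy[m])))
                if k is not None:
                    flat[m] = k
        return flat


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_occurrence_csv(path) -> OccurrenceSet:
    """Read an occurrence CSV (survey-record schema, case-insensitive headers)."""
    df = pd.read_csv(path, float_precision="round_trip")
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _HEADER_ALIASES:
            renames[col] = _HEADER_ALIASES[key]
    df = df.rename(columns=renames)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV {path} is missing required column(s): {missing}")
    df["reference"] = df["reference"].fillna("")
    return OccurrenceSet(df)


def write_occurrence_csv(occ: OccurrenceSet, path) -> None:
    df = occ.records.rename(columns={"lon": "Lon", "lat": "Lat", "occurrence": "Occurrence"})
    df.to_csv(path, index=False)


def write_coastal_csv(coastal: CoastalCellIndex, path) -> None:
    """Persist a coastal index (cell ids, grid indices, centers) with the
    grid parameters in a comment header."""
    g = coastal.grid
    centers = coastal.centers()
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(coastal)),
            "ix": [c[0] for c in coastal.cells],
            "iy": [c[1] for c in coastal.cells],
            "lon": centers[:, 0],
            "lat": centers[:, 1],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# grid lon_min={g.lon_min} lat_min={g.lat_min} "
                 f"cell_size={g.cell_size} n_lon={g.n_lon} n_lat={g.n_lat}\n")
        df.to_csv(fh, index=False)


def read_coastal_csv(path) -> CoastalCellIndex:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# grid"):
            raise ValueError(f"coastal CSV {path} lacks the grid header line")
        params = dict(tok.split("=") for tok in header.split()[2:])
        grid = GridSpec(
            lon_min=float(params["lon_min"]), lat_min=float(params["lat_min"]),
            cell_size=float(params["cell_size"]),
            n_lon=int(params["n_lon"]), n_lat=int(params["n_lat"]),
        )
        df = pd.read_csv(fh)
    cells = list(zip(df["ix"].astype(int), df["iy"].astype(int)))
    return CoastalCellIndex(grid, cells)


def read_connectivity_csv(path) -> pd.DataFrame:
    """Connectivity matrix CSV -> DataFrame with integer coastal-cell labels."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(int)
    df.columns = df.columns.astype(int)
    return df


def write_connectivity_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)


# ---------------------------------------------------------------------------
# NetCDF I/O (classic format through xarray)
# ---------------------------------------------------------------------------

def _grid_from_coords(lon: np.ndarray, lat: np.ndarray) -> GridSpec:
    """Recover a GridSpec from cell-center coordinates."""
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    if lon.size > 1:
        step = float(np.diff(lon).mean())
    elif lat.size > 1:
        step = float(np.diff(lat).mean())
    else:
        raise ValueError("cannot infer cell size from a 1x1 grid")
    # snap away last-ulp noise from coordinate arithmetic so a written grid
    # reconstructs to the exact GridSpec it came from
    step = round(step, 12)
    return GridSpec(
        lon_min=round(float(lon[0]) - step / 2, 9),
        lat_min=round(float(lat[0]) - step / 2, 9),
        cell_size=step,
        n_lon=lon.size,
        n_lat=lat.size,
    )


def write_raster_netcdf(raster: Raster2D, path) -> None:
    ds = xr.Dataset(
        {raster.name or "values": (("lat", "lon"), raster.values, {"units": raster.units})},
        coords={"lat": raster.grid.lat_centers(), "lon": raster.grid.lon_centers()},
    )
    ds.to_netcdf(path, engine="scipy")


def read_raster_netcdf(path, var: str | None = None) -> Raster2D:
    with xr.open_dataset(path, engine="scipy") as ds:
        name = var if var is not None else list(ds.data_vars)[0]
        da = ds[name]
        grid = _grid_from_coords(ds["lon"].values, ds["lat"].values)
        return Raster2D(grid, da.values.astype(float), name=name,
                        units=str(da.attrs.get("units", "")))


def write_velocity_netcdf(series: VelocityFieldSeries, path,
                          u_var: str = "water_u", v_var: str = "water_v") -> None:
    ds = xr.Dataset(
        {
            u_var: (("time", "lat", "lon"), series.u, {"units": "m s-1"}),
            v_var: (("time", "lat", "lon"), series.v, {"units": "m s-1"}),
        },
        coords={
            "time": series.dates,
            "lat": series.grid.lat_centers(),
            "lon": series.grid.lon_centers(),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_velocity_netcdf(path, u_var: str = "water_u", v_var: str = "water_v") -> VelocityFieldSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        for var in (u_var, v_var):
            if var not in ds:
                raise ValueError(f"velocity file {path} lacks variable {var!r}")
        u = ds[u_var].values.astype(float)
        v = ds[v_var].values.astype(float)
        if u.shape != v.shape:
            raise ValueError(f"u/v shapes differ: {u.shape} vs {v.shape}")
        grid = _grid_from_coords(ds["lon"].values, ds["lat"].values)
        dates = pd.DatetimeIndex(ds["time"].values)
        return VelocityFieldSeries(grid, dates, u, v)
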