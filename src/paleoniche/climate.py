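"""Gridded paleoclimate data model.

A :class:`ClimateCube` carries the five environmental variables used for
ungulate niche modelling (BIO5, BIO6, BIO12, NPP, rugosity) on a regular
lon/lat grid with an irregular time axis of "slices" (ages in calibrated
years BP): 1000-year spacing up to 22 kya and 2000-year spacing for older
slices, mirroring the structure of published late-Quaternary reconstructions.
Per-slice land and ice masks delimit the available environment: ice-covered
cells are treated as non-habitat everywhere (background sampling, availability
densities, binary-map denominators).

Cells are half-open boxes [west, east) x [south, north); stored coordinates
are cell centers. All I/O goes through xarray (NetCDF3 via the scipy engine,
so no binary-only dependency is needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

#: canonical variable order and units: degC, degC, mm/yr, gC/m2/yr, unitless
VARIABLES = ("BIO5", "BIO6", "BIO12", "NPP", "rugosity")

#: slice spacing rule (years): fine spacing up to the breakpoint, coarse after
SPACING_BREAK = 22_000
SPACING_FINE = 1_000
SPACING_COARSE = 2_000


def time_axis(young: float = 7_500, old: float = 47_000) -> np.ndarray:
    """Slice ages (years BP, ascending) covered by a time window.

    Ages are the multiples of 1000 y within [young, old] up to 22 kya and
    the multiples of 2000 y beyond, i.e. the default 7.5-47 kya window gives
    {8000, 9000, ..., 22000, 24000, ..., 46000} (27 slices).
    """
    if young >= old:
        raise ValueError("window must satisfy young < old")
    fine = np.arange(SPACING_FINE, SPACING_BREAK + 1, SPACING_FINE)
    coarse = np.arange(SPACING_BREAK + SPACING_COARSE, old + 1, SPACING_COARSE)
    ages = np.concatenate([fine, coarse]).astype(float)
    return ages[(ages >= young) & (ages <= old)]


@dataclass
class GridSpec:
    """Regular lon/lat grid; origin is the (west, south) outer corner."""

    lon_min: float
    lat_min: float
    resolution: float
    n_lon: int
    n_lat: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValueError("degenerate grid: need at least 2 cells per axis")

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    def cell_index(self, lon, lat):
        """(row, col) of the half-open cell containing each point.

        Raises IndexError naming the first offending point index if any
        point falls outside the grid.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        bad = (col < 0) | (col >= self.n_lon) | (row < 0) | (row >= self.n_lat)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise IndexError(f"point {i} (lon={lon.flat[i]}, lat={lat.flat[i]}) outside grid")
        return row, col


@dataclass
class ClimateCube:
    """Multi-variable paleoclimate time series with land/ice masks.

    Arrays are (time, lat, lon); sea cells are NaN in every variable.
    ``land`` and ``ice`` are per-slice uint8 masks.
    """

    grid: GridSpec
    ages: np.ndarray  # years BP, strictly ascending
    variables: dict  # name -> (n_time, n_lat, n_lon) float array
    land: np.ndarray  # (n_time, n_lat, n_lon) uint8
    ice: np.ndarray  # (n_time, n_lat, n_lon) uint8
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("time axis must be strictly increasing")
        shape = (len(self.ages), self.grid.n_lat, self.grid.n_lon)
        for name in VARIABLES:
            if name not in self.variables:
                raise ValueError(f"variable {name} absent")
            if self.variables[name].shape != shape:
                raise ValueError(f"variable {name} has shape {self.variables[name].shape}, expected {shape}")
        for name, mask in (("land", self.land), ("ice", self.ice)):
            if mask.shape != shape:
                raise ValueError(f"mask {name} has shape {mask.shape}, expected {shape}")
        self._check_spacing()

    def _check_spacing(self) -> None:
        for a, b in zip(self.ages[:-1], self.ages[1:]):
            expected = SPACING_FINE if b <= SPACING_BREAK else SPACING_COARSE
            if b - a != expected:
                warnings.warn(
                    f"non-standard slice spacing {b - a:.0f} y between {a:.0f} and {b:.0f}",
                    stacklevel=3,
                )
                break

    # -- lookups ---------------------------------------------------------

    def slice_index(self, age: float) -> int:
        idx = int(np.flatnonzero(self.ages == age)[0]) if age in self.ages else -1
        if idx < 0:
            raise KeyError(f"no slice at {age} years BP")
        return idx

    def available(self, age: float) -> np.ndarray:
        """Boolean (lat, lon) mask of land, ice-free cells at a slice."""
        i = self.slice_index(age)
        return (self.land[i] > 0) & (self.ice[i] == 0)

    def env_at(self, age: float) -> pd.DataFrame:
        """Environment table of all available cells at one slice."""
        i = self.slice_index(age)
        ok = self.available(age)
        rows, cols = np.nonzero(ok)
        out = pd.DataFrame(
            {
                "lon": self.grid.lons[cols],
                "lat": self.grid.lats[rows],
                "age_calBP": age,
                "time": age,
            }
        )
        for name in VARIABLES:
            out[name] = self.variables[name][i][rows, cols]
        return out

    # -- xarray bridge ---------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        coords = {"time": self.ages, "lat": self.grid.lats, "lon": self.grid.lons}
        data = {name: (("time", "lat", "lon"), self.variables[name]) for name in VARIABLES}
        data["land"] = (("time", "lat", "lon"), self.land.astype(np.uint8))
        data["ice"] = (("time", "lat", "lon"), self.ice.astype(np.uint8))
        ds = xr.Dataset(data, coords=coords, attrs=dict(self.attrs))
        ds.attrs["resolution"] = self.grid.resolution
        ds["time"].attrs["units"] = "years BP"
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateCube":
        for name in VARIABLES:
            if name not in ds.data_vars:
                raise ValueError(f"variable {name} absent")
        for name in ("land", "ice"):
            if name not in ds.data_vars:
                raise ValueError(f"mask {name} absent")
        ds = ds.sortby("time")
        lons = np.asarray(ds["lon"].values, dtype=float)
        lats = np.asarray(ds["lat"].values, dtype=float)
        res = float(ds.attrs.get("resolution", np.median(np.diff(lons))))
        grid = GridSpec(
            lon_min=float(lons[0] - res / 2),
            lat_min=float(lats[0] - res / 2),
            resolution=res,
            n_lon=len(lons),
            n_lat=len(lats),
        )
        variables = {name: np.asarray(ds[name].values, dtype=float) for name in VARIABLES}
        attrs = {k: v for k, v in ds.attrs.items() if k != "resolution"}
        return cls(
            grid=grid,
            ages=np.asarray(ds["time"].values, dtype=float),
            variables=variables,
            land=np.asarray(ds["land"].values).astype(np.uint8),
            ice=np.asarray(ds["ice"].values).astype(np.uint8),
            attrs=attrs,
        )


def write_climate_cube(cube: ClimateCube, path) -> None:
    cube.to_dataset().to_netcdf(path, engine="scipy")


def read_climate_cube(path) -> ClimateCube:
    """Read a conforming netCDF file (time/lat/lon dims, five variables,
    land+ice masks). Time order on disk is irrelevant: the axis is sorted
    ascending on load. Violations of the slice-spacing rule only warn,
    since real reconstructions may use other spacings."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return ClimateCube.from_dataset(ds.load())


# -- slice assignment ----------------------------------------------------


def nearest_slice(age, ages: np.ndarray):
    """Nearest slice age for each query age; ties go to the OLDER slice.

    Ages must lie within [youngest - half first gap, oldest + half last gap];
    anything outside raises ValueError.
    """
    ages = np.asarray(ages, dtype=float)
    scalar = np.isscalar(age)
    q = np.atleast_1d(np.asarray(age, dtype=float))
    lo = ages[0] - (ages[1] - ages[0]) / 2
    hi = ages[-1] + (ages[-1] - ages[-2]) / 2
    bad = (q < lo) | (q > hi)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"age {q[i]} outside tolerance [{lo}, {hi}] of the time axis")
    pos = np.searchsorted(ages, q)
    pos = np.clip(pos, 1, len(ages) - 1)
    left, right = ages[pos - 1], ages[pos]
    # tie (equal distance) -> older (larger age), hence strict '<' keeps right
    take_left = (q - left) < (right - q)
    out = np.where(take_left, left, right)
    out = np.where(q <= ages[0], ages[0], out)
    out = np.where(q >= ages[-1], ages[-1], out)
    return float(out[0]) if scalar else out


def extract_env(cube: ClimateCube, points: pd.DataFrame) -> pd.DataFrame:
    """Annotate (lon, lat, age) points with the five variables from the
    containing cell at the nearest slice.

    Output preserves input row order and adds ``slice_calBP``, ``status``
    ('ok'/'sea'/'ice') and one column per variable; sea/ice points get NaN
    environment but are kept (flagged, not dropped). Points outside the
    grid raise IndexError with the point index.
    """
    lon = points["lon"].to_numpy(dtype=float) if "lon" in points else points["longitude"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float) if "lat" in points else points["latitude"].to_numpy(dtype=float)
    age_col = "age_calBP" if "age_calBP" in points else "age"
    age = points[age_col].to_numpy(dtype=float)

    row, col = cube.grid.cell_index(lon, lat)
    sl = np.atleast_1d(nearest_slice(age, cube.ages))
    tidx = np.searchsorted(cube.ages, sl)

    out = points.reset_index(drop=True).copy()
    out["slice_calBP"] = sl
    is_land = cube.land[tidx, row, col] > 0
    is_ice = cube.ice[tidx, row, col] > 0
    status = np.where(~is_land, "sea", np.where(is_ice, "ice", "ok"))
    out["status"] = status
    for name in VARIABLES:
        vals = cube.variables[name][tidx, row, col]
        vals = np.where(status == "ok", vals, np.nan)
        out[name] = vals
    out["time"] = sl
    return out


# -- availability densities ----------------------------------------------


@dataclass
class DensityMatrix:
    """Per-slice density of one variable over available (land, ice-free)
    cells, on common bin edges; each column is a probability vector."""

    variable: str
    edges: np.ndarray  # n_bins + 1
    ages: np.ndarray  # n_slices
    density: np.ndarray  # (n_bins, n_slices), columns sum to 1

    def to_frame(self) -> pd.DataFrame:
        mid = (self.edges[:-1] + self.edges[1:]) / 2
        return pd.DataFrame(self.density, index=pd.Index(mid, name=self.variable),
                            columns=pd.Index(self.ages, name="age_calBP"))


def availability_density(cube: ClimateCube, variable: str, n_bins: int = 50) -> DensityMatrix:
    """Histogram of a variable's available values, per slice, with global
    (all-slice) bin edges. All-sea slices give a zero column with a warning."""
    if variable not in VARIABLES:
        raise KeyError(f"unknown variable {variable}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    arr = cube.variables[variable]
    avail = (cube.land > 0) & (cube.ice == 0)
    pool = arr[avail]
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("no available cells in any slice")
    lo, hi = float(pool.min()), float(pool.max())
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    dens = np.zeros((n_bins, len(cube.ages)))
    for i in range(len(cube.ages)):
        vals = arr[i][avail[i]]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"slice {cube.ages[i]:.0f}: no available cells, zero density column")
            continue
        h, _ = np.histogram(vals, bins=edges)
        dens[:, i] = h / h.sum()
    return DensityMatrix(variable=variable, edges=edges, ages=cube.ages.copy(), density=dens)
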