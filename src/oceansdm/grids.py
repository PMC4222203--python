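"""Gridded environmental layers: data model, file I/O, regridding, units.

Grids are regular lat/lon rasters with cell-center coordinates, ascending
latitude and longitude axes, longitudes in [-180, 180), and an explicit
ocean mask. Two on-disk formats are supported: ESRI ASCII grid (plain text,
``NODATA_value`` sentinel) and classic NetCDF (via :mod:`scipy.io`).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.io import netcdf_file

from .errors import AlignmentError, FormatError, InputError, UnitError

#: Sentinel written to ASCII grids (and used as NetCDF fill value).
NODATA = -9999.0

#: Canonical units per known variable name.
CANONICAL_UNITS = {
    "sst": "degC",
    "salinity": "PSU",
    "nitrate": "umol/L",
    "silicate": "umol/L",
    "bias": "1",
    "suitability": "1",
    "count": "1",
}

#: Fixed covariate ordering used when assembling sample matrices.
VARIABLE_ORDER = ("sst", "salinity", "nitrate", "silicate")

_COORD_TOL = 1e-6


def _uniform_step(centers: np.ndarray, axis_name: str) -> float:
    if centers.size < 2:
        raise FormatError(f"{axis_name} axis needs at least 2 points")
    diffs = np.diff(centers)
    step = diffs[0]
    if step <= 0 or not np.allclose(diffs, step, atol=1e-6, rtol=1e-6):
        raise FormatError(f"irregular {axis_name} spacing")
    return float(step)


@dataclass
class EnvGrid:
    """One environmental variable on a regular masked lat/lon grid.

    ``values`` is a (nlat, nlon) float array holding NaN exactly where
    ``mask`` is False (land); ``mask`` is True on ocean cells.
    """

    variable: str
    units: str
    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        _uniform_step(self.lat, "lat")
        _uniform_step(self.lon, "lon")
        if self.lon.min() < -180.0 - _COORD_TOL or self.lon.max() >= 180.0 + _COORD_TOL:
            raise FormatError("longitudes must lie in [-180, 180)")
        shape = (self.lat.size, self.lon.size)
        if self.values.shape != shape or self.mask.shape != shape:
            raise FormatError(
                f"values/mask shape {self.values.shape} does not match axes {shape}"
            )
        self.values = np.where(self.mask, self.values, np.nan)

    # -- geometry helpers -------------------------------------------------

    @property
    def lat_step(self) -> float:
        return _uniform_step(self.lat, "lat")

    @property
    def lon_step(self) -> float:
        return _uniform_step(self.lon, "lon")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    def same_geometry(self, other: "EnvGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=_COORD_TOL)
            and np.allclose(self.lon, other.lon, atol=_COORD_TOL)
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell containing a point: nearest center, half-open toward +lon/+lat.

        Returns None when the point falls outside the grid's bounding box.
        """
        i = int(np.floor((lat - (self.lat[0] - self.lat_step / 2.0)) / self.lat_step))
        j = int(np.floor((lon - (self.lon[0] - self.lon_step / 2.0)) / self.lon_step))
        if 0 <= i < self.lat.size and 0 <= j < self.lon.size:
            return i, j
        return None

    def with_values(
        self, values: np.ndarray, variable: str | None = None, units: str | None = None,
        mask: np.ndarray | None = None,
    ) -> "EnvGrid":
        """A copy of this geometry carrying new values (and optional new mask)."""
        return EnvGrid(
            variable=variable or self.variable,
            units=units if units is not None else self.units,
            lat=self.lat.copy(),
            lon=self.lon.copy(),
            values=np.asarray(values, dtype=float),
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
        )


@dataclass
class EnvStack:
    """Aligned multi-variable grid set for one time slice / scenario / GCM."""

    grids: dict[str, EnvGrid]
    time_tag: str = "annual"  # "annual" or "month01".."month12"
    scenario_tag: str = "present"
    gcm_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.grids:
            raise AlignmentError("stack needs at least one grid")
        ref = next(iter(self.grids.values()))
        for name, g in self.grids.items():
            if name != g.variable:
                raise AlignmentError(f"key {name!r} does not match variable {g.variable!r}")
            if not g.same_geometry(ref):
                raise AlignmentError(f"variable {name!r} has mismatched geometry")
            if not np.array_equal(g.mask, ref.mask):
                raise AlignmentError(f"variable {name!r} has mismatched mask")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.grids)

    @property
    def lat(self) -> np.ndarray:
        return next(iter(self.grids.values())).lat

    @property
    def lon(self) -> np.ndarray:
        return next(iter(self.grids.values())).lon

    @property
    def mask(self) -> np.ndarray:
        return next(iter(self.grids.values())).mask

    @property
    def month(self) -> int | None:
        if self.time_tag.startswith("month"):
            return int(self.time_tag[5:])
        return None

    def reference(self) -> EnvGrid:
        return next(iter(self.grids.values()))

    def values_at(self, cells: Sequence[tuple[int, int]], variables: Sequence[str]) -> np.ndarray:
        """Covariate rows (len(cells) x len(variables)) at the given cell indices."""
        for v in variables:
            if v not in self.grids:
                raise InputError(f"stack lacks variable {v!r}")
        ii = np.asarray([c[0] for c in cells], dtype=int)
        jj = np.asarray([c[1] for c in cells], dtype=int)
        return np.column_stack([self.grids[v].values[ii, jj] for v in variables])

    def map_values(self, variables: Sequence[str]) -> np.ndarray:
        """Covariate rows for every ocean cell, in mask scan order."""
        ii, jj = np.nonzero(self.mask)
        return self.values_at(list(zip(ii, jj)), variables)


def month_tag(m: int) -> str:
    if not 1 <= int(m) <= 12:
        raise InputError(f"month out of range: {m}")
    return f"month{int(m):02d}"


# ---------------------------------------------------------------------------
# unit harmonization

_TO_CANONICAL = {
    # temperature
    "degC": ("degC", lambda v: v),
    "°C": ("degC", lambda v: v),
    "celsius": ("degC", lambda v: v),
    "K": ("degC", lambda v: v - 273.15),
    "kelvin": ("degC", lambda v: v - 273.15),
    # salinity
    "PSU": ("PSU", lambda v: v),
    "psu": ("PSU", lambda v: v),
    # nutrients
    "umol/L": ("umol/L", lambda v: v),
    "µmol L⁻¹": ("umol/L", lambda v: v),
    "umol l-1": ("umol/L", lambda v: v),
    "mol/m^3": ("umol/L", lambda v: v * 1000.0),
    "mol m-3": ("umol/L", lambda v: v * 1000.0),
    # dimensionless
    "1": ("1", lambda v: v),
    "dimensionless": ("1", lambda v: v),
    "": ("1", lambda v: v),
}


def harmonize_units(grid: EnvGrid, declared_units: str | None = None) -> EnvGrid:
    """Convert a grid's values to canonical units (degC, PSU, umol/L, 1).

    Idempotent: a grid already in canonical units is returned unchanged in
    value. Unknown units raise :class:`UnitError`.
    """
    units = declared_units if declared_units is not None else grid.units
    if units not in _TO_CANONICAL:
        raise UnitError(f"unknown units {units!r}")
    canon, conv = _TO_CANONICAL[units]
    return grid.with_values(conv(grid.values), units=canon)


# ---------------------------------------------------------------------------
# file I/O

def _normalize_longitudes(lon: np.ndarray, values: np.ndarray, mask: np.ndarray):
    """Map longitudes into [-180, 180) and re-sort columns ascending."""
    lon = ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0
    order = np.argsort(lon, kind="stable")
    return lon[order], values[:, order], mask[:, order]


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".nc", ".cdf", ".netcdf"):
        return "netcdf"
    return "ascii_grid"


def read_grid(
    path: str,
    format: str | None = None,
    variable: str = "sst",
    units: str | None = None,
) -> EnvGrid:
    """Read an environmental grid from ASCII-grid or NetCDF.

    Longitudes are normalized to [-180, 180); missing cells (sentinel or
    fill value) become masked. ``units`` overrides any units found in the
    file; when neither is given the canonical units for ``variable`` apply.
    """
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        return _read_ascii(path, variable, units)
    if fmt == "netcdf":
        return _read_netcdf(path, variable, units)
    raise FormatError(f"unknown format {fmt!r}")


def write_grid(grid: EnvGrid, path: str, format: str | None = None) -> None:
    """Write a grid so that :func:`read_grid` round-trips it (<=1e-6)."""
    fmt = _infer_format(path, format)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    elif fmt == "netcdf":
        _write_netcdf(grid, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def _read_ascii(path: str, variable: str, units: str | None) -> EnvGrid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise FormatError(f"ASCII grid header incomplete in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", NODATA)
    data = np.concatenate(rows)
    if data.size != ncols * nrows:
        raise FormatError(f"ASCII grid data size mismatch in {path}")
    values = data.reshape(nrows, ncols)[::-1]  # file rows run north->south
    step = header["cellsize"]
    lat = header["yllcorner"] + step * (np.arange(nrows) + 0.5)
    lon = header["xllcorner"] + step * (np.arange(ncols) + 0.5)
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    lon, values, mask = _normalize_longitudes(lon, values, mask)
    resolved = units or CANONICAL_UNITS.get(variable, "1")
    return EnvGrid(variable=variable, units=resolved, lat=lat, lon=lon, values=values, mask=mask)


def _write_ascii(grid: EnvGrid, path: str) -> None:
    step = grid.lat_step
    if abs(step - grid.lon_step) > _COORD_TOL:
        raise FormatError("ASCII grid requires square cells")
    out = np.where(grid.mask, grid.values, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.lon.size}\n")
        fh.write(f"nrows {grid.lat.size}\n")
        fh.write(f"xllcorner {grid.lon[0] - step / 2.0:.10g}\n")
        fh.write(f"yllcorner {grid.lat[0] - step / 2.0:.10g}\n")
        fh.write(f"cellsize {step:.10g}\n")
        fh.write(f"NODATA_value {NODATA:.10g}\n")
        for row in out[::-1]:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def _read_netcdf(path: str, variable: str, units: str | None) -> EnvGrid:
    with netcdf_file(path, "r", mmap=False) as nc:
        if "lat" not in nc.variables or "lon" not in nc.variables:
            raise FormatError(f"NetCDF file {path} lacks lat/lon coordinates")
        lat = np.array(nc.variables["lat"][:], dtype=float)
        lon = np.array(nc.variables["lon"][:], dtype=float)
        if variable not in nc.variables:
            raise FormatError(f"NetCDF file {path} lacks variable {variable!r}")
        var = nc.variables[variable]
        values = np.array(var[:], dtype=float)
        fill = getattr(var, "_FillValue", NODATA)
        fill = float(np.asarray(fill).ravel()[0])
        file_units = getattr(var, "units", b"")
        if isinstance(file_units, bytes):
            file_units = file_units.decode()
    if lat.size >= 2 and lat[1] < lat[0]:
        lat = lat[::-1]
        values = values[::-1]
    mask = np.isfinite(values) & ~np.isclose(values, fill)
    values = np.where(mask, values, np.nan)
    lon, values, mask = _normalize_longitudes(lon, values, mask)
    resolved = units or file_units or CANONICAL_UNITS.get(variable, "1")
    return EnvGrid(variable=variable, units=resolved, lat=lat, lon=lon, values=values, mask=mask)


def _write_netcdf(grid: EnvGrid, path: str) -> None:
    with netcdf_file(path, "w") as nc:
        nc.createDimension("lat", grid.lat.size)
        nc.createDimension("lon", grid.lon.size)
        vlat = nc.createVariable("lat", "d", ("lat",))
        vlat[:] = grid.lat
        vlat.units = "degrees_north"
        vlon = nc.createVariable("lon", "d", ("lon",))
        vlon[:] = grid.lon
        vlon.units = "degrees_east"
        var = nc.createVariable(grid.variable, "d", ("lat", "lon"))
        var[:] = np.where(grid.mask, grid.values, NODATA)
        var.units = grid.units
        var._FillValue = NODATA


# ---------------------------------------------------------------------------
# regridding

def regrid(grid: EnvGrid, like: EnvGrid, method: str = "bilinear") -> EnvGrid:
    """Interpolate a grid onto the geometry of ``like``.

    Bilinear interpolation is mask-weighted: a target cell is masked when
    its whole interpolation stencil is land, and land never contributes a
    value. Nearest assigns the geometrically nearest source cell.
    """
    if method not in ("bilinear", "nearest"):
        raise InputError(f"unknown regrid method {method!r}")
    if (
        like.lat[0] > grid.lat[-1] + _COORD_TOL
        or like.lat[-1] < grid.lat[0] - _COORD_TOL
        or like.lon[0] > grid.lon[-1] + _COORD_TOL
        or like.lon[-1] < grid.lon[0] - _COORD_TOL
    ):
        raise InputError("source and target domains do not overlap")

    tlat, tlon = np.meshgrid(like.lat, like.lon, indexing="ij")
    pts = np.column_stack([tlat.ravel(), tlon.ravel()])
    if method == "nearest":
        interp = RegularGridInterpolator(
            (grid.lat, grid.lon), grid.values, method="nearest",
            bounds_error=False, fill_value=np.nan,
        )
        vals = interp(pts).reshape(like.shape)
        ocean = np.isfinite(vals)
    else:
        weight = grid.mask.astype(float)
        filled = np.where(grid.mask, grid.values, 0.0)
        iv = RegularGridInterpolator(
            (grid.lat, grid.lon), filled, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        iw = RegularGridInterpolator(
            (grid.lat, grid.lon), weight, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        num = iv(pts).reshape(like.shape)
        den = iw(pts).reshape(like.shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / den
        ocean = np.isfinite(den) & (den > 0)
        vals = np.where(ocean, vals, np.nan)
    mask = ocean & like.mask
    return EnvGrid(
        variable=grid.variable, units=grid.units,
        lat=like.lat.copy(), lon=like.lon.copy(),
        values=np.where(mask, vals, np.nan), mask=mask,
    )


# ---------------------------------------------------------------------------
# stacking

def align_stack(
    grids: Iterable[EnvGrid],
    time_tag: str = "annual",
    scenario_tag: str = "present",
    gcm_tag: str | None = None,
) -> EnvStack:
    """Assemble grids into a stack, intersecting their ocean masks.

    All grids must share geometry exactly; a cell is ocean in the stack only
    if it is ocean in every member.
    """
    grids = list(grids)
    if not grids:
        raise AlignmentError("cannot stack zero grids")
    ref = grids[0]
    names = [g.variable for g in grids]
    if len(set(names)) != len(names):
        raise AlignmentError(f"duplicate variables in stack: {names}")
    mask = ref.mask.copy()
    for g in grids[1:]:
        if not g.same_geometry(ref):
            raise AlignmentError(f"variable {g.variable!r} has mismatched geometry")
        mask &= g.mask
    members = {
        g.variable: g.with_values(np.where(mask, g.values, np.nan), mask=mask)
        for g in grids
    }
    return EnvStack(grids=members, time_tag=time_tag, scenario_tag=scenario_tag, gcm_tag=gcm_tag)
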