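"""Raster I/O: single-band GeoTIFF and CF-style NetCDF.

High-resolution products travel as single-band GeoTIFFs in the WGS84
geographic CRS (EPSG:4326), float32 for physical values or int16/int32
for the integer-encoded layers, with nodata serialized as a sentinel
recorded in the GDAL nodata tag.  Coarse GCM climatologies may instead
arrive as one NetCDF file with ``lat``/``lon``/``time`` dimensions; both
read paths yield identical :class:`~paleodown.grid.GeoGrid` semantics.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import tifffile
from scipy.io import netcdf_file

from .errors import FormatError
from .grid import GeoGrid, GridSpec, MonthlyStack

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024  # 2 = geographic
_GT_RASTER_TYPE = 1025  # 1 = PixelIsArea
_GEOGRAPHIC_TYPE = 2048  # 4326 = WGS84

_DEFAULT_NODATA = {
    "float32": -9999.0,
    "float64": -9999.0,
    "int16": -32768,
    "int32": -2147483648,
}


def write_geotiff(grid: GeoGrid, path: str | os.PathLike, dtype=None) -> Path:
    """Write a GeoGrid as a single-band WGS84 GeoTIFF.

    ``dtype`` defaults to float32 for floating grids and the grid's own
    integer type otherwise.  Nodata cells are stored as a sentinel value
    recorded in the GDAL nodata tag; units travel in the image
    description.
    """
    path = Path(path)
    if dtype is None:
        dtype = "float32" if np.issubdtype(grid.values.dtype, np.floating) else str(
            grid.values.dtype
        )
    dtype = np.dtype(dtype)
    if dtype.name not in _DEFAULT_NODATA:
        raise FormatError(f"unsupported pixel type {dtype.name}")
    nodata = _DEFAULT_NODATA[dtype.name]
    data = grid.values.astype(dtype)
    data[grid.mask] = nodata

    geokeys = (
        1, 1, 0, 3,
        _GT_MODEL_TYPE, 0, 1, 2,
        _GT_RASTER_TYPE, 0, 1, 1,
        _GEOGRAPHIC_TYPE, 0, 1, 4326,
    )
    spec = grid.spec
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size_lon, spec.cell_size_lat, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.lon_origin, spec.lat_origin, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, repr(nodata)),
    ]
    tifffile.imwrite(
        path,
        data,
        extratags=extratags,
        description=json.dumps({"units": grid.units}),
    )
    return path


def read_geotiff(path: str | os.PathLike) -> GeoGrid:
    """Read a single-band WGS84 geographic GeoTIFF into a GeoGrid."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = {}
        for t in page.tags.values():
            tags.setdefault(t.code, t.value)
        data = page.asarray()

    if _GEO_KEY_DIRECTORY not in tags:
        raise FormatError(f"{path}: missing GeoKeyDirectory; not a GeoTIFF")
    keys = _parse_geokeys(tags[_GEO_KEY_DIRECTORY])
    if keys.get(_GT_MODEL_TYPE) != 2:
        raise FormatError(
            f"{path}: CRS model type {keys.get(_GT_MODEL_TYPE)} is not geographic"
        )
    gcs = keys.get(_GEOGRAPHIC_TYPE)
    if gcs not in (None, 4326):
        raise FormatError(f"{path}: geographic CRS {gcs} is not WGS84 (4326)")
    if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
        raise FormatError(f"{path}: missing pixel scale / tiepoint georeferencing")

    sx, sy = tags[_MODEL_PIXEL_SCALE][:2]
    ti = tags[_MODEL_TIEPOINT]
    # tiepoint maps raster (i, j, k) -> model (x, y, z)
    lon_origin = ti[3] - ti[0] * sx
    lat_origin = ti[4] + ti[1] * sy

    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single band, got shape {data.shape}")
    spec = GridSpec(
        lat_origin=float(lat_origin),
        lon_origin=float(lon_origin),
        cell_size_lat=float(sy),
        cell_size_lon=float(sx),
        n_rows=data.shape[0],
        n_cols=data.shape[1],
    )

    mask = np.zeros(data.shape, dtype=bool)
    if _GDAL_NODATA in tags:
        sentinel = float(tags[_GDAL_NODATA])
        if np.issubdtype(data.dtype, np.floating):
            mask = data == np.asarray(sentinel, dtype=data.dtype)
        else:
            mask = data == int(sentinel)
    if np.issubdtype(data.dtype, np.floating):
        mask |= ~np.isfinite(data)
        data = np.where(mask, 0, data)

    units = ""
    desc = tags.get(270)
    if desc:
        try:
            units = json.loads(desc).get("units", "")
        except (json.JSONDecodeError, AttributeError):
            units = ""
    return GeoGrid(spec, data, mask, units)


def _parse_geokeys(directory) -> dict[int, int]:
    d = list(directory)
    n_keys = d[3]
    keys = {}
    for k in range(n_keys):
        key_id, location, count, value = d[4 + 4 * k : 8 + 4 * k]
        if location == 0:
            keys[key_id] = value
    return keys


def write_grid(grid: GeoGrid, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a grid, dispatching on ``format`` or the file extension."""
    fmt = format or _infer_format(path)
    if fmt == "geotiff":
        return write_geotiff(grid, path)
    raise FormatError(f"unknown raster format {fmt!r}")


def read_grid(path: str | os.PathLike, format: str | None = None) -> GeoGrid:
    """Read a grid, dispatching on ``format`` or the file extension."""
    fmt = format or _infer_format(path)
    if fmt == "geotiff":
        return read_geotiff(path)
    raise FormatError(f"unknown raster format {fmt!r}")


def _infer_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix == ".nc":
        return "netcdf"
    raise FormatError(f"cannot infer raster format from {path}")


# ---------------------------------------------------------------------------
# Monthly stacks: a directory of 12 GeoTIFFs, or one CF-style NetCDF file.
# ---------------------------------------------------------------------------

def write_monthly_geotiffs(
    stack: MonthlyStack, directory: str | os.PathLike, prefix: str | None = None
) -> list[Path]:
    """Write 12 GeoTIFFs named ``<prefix>_01.tif`` ... ``<prefix>_12.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or stack.variable
    return [
        write_geotiff(g, directory / f"{prefix}_{m + 1:02d}.tif")
        for m, g in enumerate(stack.months)
    ]


def read_monthly_geotiffs(
    directory: str | os.PathLike, variable: str, prefix: str | None = None
) -> MonthlyStack:
    directory = Path(directory)
    prefix = prefix or variable
    months = [read_geotiff(directory / f"{prefix}_{m + 1:02d}.tif") for m in range(12)]
    return MonthlyStack(variable, months)


def write_netcdf_stack(stack: MonthlyStack, path: str | os.PathLike) -> Path:
    """Write a MonthlyStack as a NetCDF-3 file with lat/lon/time dimensions."""
    path = Path(path)
    spec = stack.spec
    fill = np.float32(_DEFAULT_NODATA["float32"])
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("time", 12)
        nc.createDimension("lat", spec.n_rows)
        nc.createDimension("lon", spec.n_cols)
        vt = nc.createVariable("time", "i", ("time",))
        vt[:] = np.arange(1, 13)
        vt.units = "month"
        vlat = nc.createVariable("lat", "d", ("lat",))
        vlat[:] = spec.lat_centers()
        vlat.units = "degrees_north"
        vlon = nc.createVariable("lon", "d", ("lon",))
        vlon[:] = spec.lon_centers(normalize=False)
        vlon.units = "degrees_east"
        var = nc.createVariable(stack.variable, "f", ("time", "lat", "lon"))
        cube = stack.as_array().astype(np.float32)
        cube[stack.mask_array()] = fill
        var[:] = cube
        # NetCDF-3 attributes must be ASCII; degree sign maps to CF spelling
        var.units = stack.units.replace("°C", "degC")
        var._FillValue = fill
    return path


def read_netcdf_stack(path: str | os.PathLike, variable: str) -> MonthlyStack:
    """Read a 12-month climatology from a CF-style NetCDF-3 file.

    Latitudes may be stored ascending or descending; the stack is
    returned north-to-south either way.
    """
    with netcdf_file(str(path), "r", mmap=False) as nc:
        if variable not in nc.variables:
            raise FormatError(f"{path}: no variable {variable!r}")
        lat = np.array(nc.variables["lat"][:], dtype=float)
        lon = np.array(nc.variables["lon"][:], dtype=float)
        v = nc.variables[variable]
        cube = np.array(v[:], dtype=float)
        fill = float(v._FillValue) if hasattr(v, "_FillValue") else None
        units = v.units.decode() if isinstance(getattr(v, "units", ""), bytes) else str(
            getattr(v, "units", "")
        )
        if units == "degC":
            units = "°C"

    if cube.shape[0] != 12:
        raise FormatError(f"{path}: expected 12 time steps, got {cube.shape[0]}")
    dlat = np.diff(lat)
    dlon = np.diff(lon)
    if not (np.allclose(dlat, dlat[0]) and np.allclose(dlon, dlon[0])):
        raise FormatError(f"{path}: lat/lon are not regularly spaced")
    if dlat[0] > 0:  # south-to-north on disk; flip
        lat = lat[::-1]
        cube = cube[:, ::-1, :]
    step_lat = -float(np.diff(lat)[0])
    step_lon = float(dlon[0])
    spec = GridSpec(
        lat_origin=float(lat[0]) + step_lat / 2,
        lon_origin=float(lon[0]) - step_lon / 2,
        cell_size_lat=step_lat,
        cell_size_lon=step_lon,
        n_rows=lat.size,
        n_cols=lon.size,
    )
    mask = ~np.isfinite(cube)
    if fill is not None:
        mask |= np.isclose(cube, fill, rtol=1e-6)
    cube = np.where(mask, 0.0, cube)
    return MonthlyStack.from_array(variable, spec, cube, mask, units)
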