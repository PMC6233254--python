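"""Regular latitude/longitude raster containers and grid arithmetic.

Everything in the package moves through three carriers defined here:

``GridSpec``
    The geometry of a regular WGS84 geographic grid.  Row 0 is the
    northernmost row, column 0 the westernmost column, and coordinates
    refer to cell *centers*; cell intervals are half-open on their
    south/east edges.

``GeoGrid``
    A single raster: a ``GridSpec`` plus a value matrix, an explicit
    nodata mask (``True`` marks missing cells) and a free-text unit.

``MonthlyStack``
    Twelve ``GeoGrid`` layers of one climate variable in January-first
    order, all sharing one spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import GeometryError

#: Variables a MonthlyStack may carry.
VARIABLES = ("tmean", "tmin", "tmax", "precip")

WGS84 = "WGS84 geographic"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon grid (WGS84 geographic).

    Parameters
    ----------
    lat_origin : float
        Latitude of the northern edge of the grid, degrees.
    lon_origin : float
        Longitude of the western edge, degrees.
    cell_size_lat, cell_size_lon : float
        Cell height / width in degrees (positive).
    n_rows, n_cols : int
        Grid dimensions.
    """

    lat_origin: float
    lon_origin: float
    cell_size_lat: float
    cell_size_lon: float
    n_rows: int
    n_cols: int
    crs: str = WGS84

    def __post_init__(self) -> None:
        if self.cell_size_lat <= 0 or self.cell_size_lon <= 0:
            raise GeometryError("cell sizes must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise GeometryError("grid dimensions must be positive")
        if self.n_rows * self.cell_size_lat > 180 + 1e-9:
            raise GeometryError("grid spans more than 180 degrees of latitude")
        if self.n_cols * self.cell_size_lon > 360 + 1e-9:
            raise GeometryError("grid spans more than 360 degrees of longitude")
        if self.crs != WGS84:
            raise GeometryError(f"unsupported CRS {self.crs!r}; only {WGS84!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (strictly decreasing)."""
        i = np.arange(self.n_rows)
        return self.lat_origin - (i + 0.5) * self.cell_size_lat

    def lon_centers(self, normalize: bool = True) -> np.ndarray:
        """Cell-center longitudes, west to east; normalized to [-180, 180)."""
        j = np.arange(self.n_cols)
        lon = self.lon_origin + (j + 0.5) * self.cell_size_lon
        return normalize_lon(lon) if normalize else lon

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) matrices of all cell centers, shape ``self.shape``."""
        lat = np.repeat(self.lat_centers()[:, None], self.n_cols, axis=1)
        lon = np.repeat(self.lon_centers()[None, :], self.n_rows, axis=0)
        return lat, lon

    def refine(self, factor: int) -> "GridSpec":
        """The spec with every cell split ``factor`` × ``factor``."""
        if factor < 1 or factor != int(factor):
            raise GeometryError("refinement factor must be a positive integer")
        return replace(
            self,
            cell_size_lat=self.cell_size_lat / factor,
            cell_size_lon=self.cell_size_lon / factor,
            n_rows=self.n_rows * factor,
            n_cols=self.n_cols * factor,
        )


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def cell_center(spec: GridSpec, row: int, col: int) -> tuple[float, float]:
    """Geographic center of cell (row, col); longitude wrapped to [-180, 180).

    Raises
    ------
    IndexError
        If the indices fall outside the grid.
    """
    if not (0 <= row < spec.n_rows):
        raise IndexError(f"row {row} outside [0, {spec.n_rows})")
    if not (0 <= col < spec.n_cols):
        raise IndexError(f"col {col} outside [0, {spec.n_cols})")
    lat = spec.lat_origin - (row + 0.5) * spec.cell_size_lat
    lon = float(normalize_lon(spec.lon_origin + (col + 0.5) * spec.cell_size_lon))
    return (lat, lon)


def downscale_factor(coarse: GridSpec, fine: GridSpec, rtol: float = 1e-9) -> int:
    """Integer linear refinement factor between a coarse and a fine spec.

    The factor is the ratio of cell sizes, which must be the same integer
    in latitude and longitude (e.g. 2.5 arc-degrees over 2.5 arc-minutes
    gives 60).  Origins must coincide.
    """
    r_lat = coarse.cell_size_lat / fine.cell_size_lat
    r_lon = coarse.cell_size_lon / fine.cell_size_lon
    f_lat, f_lon = round(r_lat), round(r_lon)
    if abs(r_lat - f_lat) > rtol * r_lat or abs(r_lon - f_lon) > rtol * r_lon:
        raise GeometryError(
            f"cell-size ratios ({r_lat:g}, {r_lon:g}) are not integers"
        )
    if f_lat != f_lon:
        raise GeometryError(f"anisotropic refinement {f_lat} != {f_lon}")
    if abs(coarse.lat_origin - fine.lat_origin) > rtol or abs(
        coarse.lon_origin - fine.lon_origin
    ) > rtol:
        raise GeometryError("coarse and fine origins are not aligned")
    if fine.n_rows != coarse.n_rows * f_lat or fine.n_cols != coarse.n_cols * f_lon:
        raise GeometryError("fine grid does not tile the coarse grid exactly")
    return f_lat


@dataclass
class GeoGrid:
    """A single raster layer: values + nodata mask on a :class:`GridSpec`.

    ``mask`` is ``True`` where the cell holds no data.  Values must be
    finite wherever the mask is ``False``.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )
        if self.mask is None:
            self.mask = np.zeros(self.spec.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise GeometryError("mask shape does not match spec shape")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values[~self.mask])
        ):
            raise GeometryError("non-finite values outside the nodata mask")

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def copy(self) -> "GeoGrid":
        return GeoGrid(self.spec, self.values.copy(), self.mask.copy(), self.units)

    def equals(self, other: "GeoGrid") -> bool:
        return (
            self.spec == other.spec
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(self.values[~self.mask], other.values[~other.mask])
        )


@dataclass
class MonthlyStack:
    """Twelve monthly layers of one variable, January first."""

    variable: str
    months: Sequence[GeoGrid]

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; one of {VARIABLES}")
        self.months = list(self.months)
        if len(self.months) != 12:
            raise GeometryError(f"a MonthlyStack needs 12 layers, got {len(self.months)}")
        spec = self.months[0].spec
        for m, g in enumerate(self.months):
            if g.spec != spec:
                raise GeometryError(f"month {m + 1} is on a different grid")
        if self.variable == "precip":
            for m, g in enumerate(self.months):
                if np.any(g.values[~g.mask] < 0):
                    raise ValueError(f"negative precipitation in month {m + 1}")

    @property
    def spec(self) -> GridSpec:
        return self.months[0].spec

    @property
    def units(self) -> str:
        return self.months[0].units

    def as_array(self) -> np.ndarray:
        """(12, n_rows, n_cols) value cube (mask not applied)."""
        return np.stack([g.values for g in self.months])

    def mask_array(self) -> np.ndarray:
        return np.stack([g.mask for g in self.months])

    @classmethod
    def from_array(
        cls,
        variable: str,
        spec: GridSpec,
        cube: np.ndarray,
        mask: np.ndarray | None = None,
        units: str = "",
    ) -> "MonthlyStack":
        cube = np.asarray(cube)
        if cube.shape != (12, spec.n_rows, spec.n_cols):
            raise GeometryError("cube must have shape (12, n_rows, n_cols)")
        if mask is None:
            mask = np.zeros(cube.shape, dtype=bool)
        months = [GeoGrid(spec, cube[m], mask[m], units) for m in range(12)]
        return cls(variable, months)


def aggregate_mean(fine: GeoGrid, coarse_spec: GridSpec) -> GeoGrid:
    """Block-average a fine grid onto an aligned coarser grid.

    Each coarse cell must be the exact union of whole fine cells (integer
    cell-size ratio, coincident origins).  The coarse value is the
    unweighted arithmetic mean of the valid fine values inside the block;
    a block with no valid fine cell becomes nodata.
    """
    factor = downscale_factor(coarse_spec, fine.spec)
    r, c = coarse_spec.shape
    vals = np.where(fine.mask, 0.0, fine.values.astype(float))
    valid = (~fine.mask).astype(float)
    # (r, factor, c, factor) block view
    vs = vals.reshape(r, factor, c, factor).sum(axis=(1, 3))
    ns = valid.reshape(r, factor, c, factor).sum(axis=(1, 3))
    mask = ns == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(mask, 0.0, vs / np.where(ns == 0, 1.0, ns))
    return GeoGrid(coarse_spec, mean, mask, fine.units)


# ---------------------------------------------------------------------------
# Spherical geometry helpers shared by the spline and sea-level modules.
# ---------------------------------------------------------------------------

def unit_vectors(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Unit vectors on the sphere for arrays of lat/lon in degrees.

    Chord distance between unit vectors is monotone in great-circle arc
    length, so k-nearest-neighbour queries in this embedding respect the
    arc metric, including longitude wraparound across the antimeridian.
    """
    la = np.deg2rad(np.asarray(lat, dtype=float))
    lo = np.deg2rad(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1
    )


def arc_degrees_from_dot(dot: np.ndarray) -> np.ndarray:
    """Great-circle arc length in degrees from dot products of unit vectors."""
    return np.rad2deg(np.arccos(np.clip(dot, -1.0, 1.0)))


def arc_degrees(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in degrees between two sets of points."""
    u = unit_vectors(lat1, lon1)
    v = unit_vectors(lat2, lon2)
    return arc_degrees_from_dot(np.sum(u * v, axis=-1))
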