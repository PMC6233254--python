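"""Paleo sea-level coastline adjustment.

A paleo period's mean sea level may sit above or below the modern one
(+25 m for the mid-Pliocene Warm Period, −40 m for the M2 glacial).
Given a modern bathymetry/elevation grid in metres, a cell is paleo land
exactly when its elevation exceeds the sea-level offset.  Lowered seas
expose continental shelf that the modern baseline climatology does not
cover; those cells are filled from the nearest modern-land cell and
flagged in a provenance band so users can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, UnitError
from .grid import (
    GeoGrid,
    MonthlyStack,
    arc_degrees_from_dot,
    unit_vectors,
)

_METRE_ALIASES = {"m", "metre", "meter", "metres", "meters"}

#: Provenance codes written alongside filled baselines.
PROVENANCE_ORIGINAL = 0
PROVENANCE_FILLED = 1


@dataclass(frozen=True)
class SeaLevelScenario:
    """Mean sea level of the paleo period, metres above pre-industrial."""

    offset_m: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset_m):
            raise ValueError("sea-level offset must be finite")


def paleo_landmask(bathymetry: GeoGrid, scenario: SeaLevelScenario) -> GeoGrid:
    """Boolean land mask: land exactly where elevation > offset.

    The bathymetry grid must be in metres relative to the modern sea
    level (negative below it).  Nodata cells are treated as ocean.
    """
    if bathymetry.units not in _METRE_ALIASES:
        raise UnitError(
            f"bathymetry must be in metres, got units {bathymetry.units!r}"
        )
    land = (bathymetry.values > scenario.offset_m) & ~bathymetry.mask
    return GeoGrid(bathymetry.spec, land, units="landmask")


def extend_baseline_to_new_land(
    baseline: MonthlyStack,
    modern_mask: GeoGrid,
    paleo_mask: GeoGrid,
) -> tuple[MonthlyStack, GeoGrid]:
    """Restrict a baseline to the paleo landmask, filling newly exposed land.

    Cells that are land in both masks keep their baseline values; cells
    land only in the paleo mask take the values of the nearest
    modern-land cell (great-circle distance, ties broken by distance,
    then latitude descending, then longitude ascending); paleo-ocean
    cells become nodata.  Returns the adjusted stack and a provenance
    grid (0 original land, 1 filled, nodata over paleo ocean).
    """
    spec = baseline.spec
    if modern_mask.spec != spec or paleo_mask.spec != spec:
        raise ConfigurationError("masks and baseline must share one grid")
    modern = modern_mask.values.astype(bool)
    paleo = paleo_mask.values.astype(bool)
    new_land = paleo & ~modern
    if new_land.any() and not modern.any():
        raise ConfigurationError("no modern land to fill newly exposed cells from")

    cube = baseline.as_array().astype(float).copy()
    mask = baseline.mask_array().copy()

    fill_src = None
    if new_land.any():
        lat, lon = spec.center_mesh()
        land_idx = np.flatnonzero(modern.ravel())
        land_uv = unit_vectors(lat.ravel()[land_idx], lon.ravel()[land_idx])
        tree = cKDTree(land_uv)
        tgt_idx = np.flatnonzero(new_land.ravel())
        tgt_uv = unit_vectors(lat.ravel()[tgt_idx], lon.ravel()[tgt_idx])
        k = min(4, land_idx.size)
        _, nn = tree.query(tgt_uv, k=k)
        nn = np.atleast_2d(nn)
        cand = land_idx[nn]  # flat indices of candidate source cells
        dot = np.einsum("qd,qkd->qk", tgt_uv, land_uv[nn])
        dist = arc_degrees_from_dot(dot)
        cl = lat.ravel()[cand]
        cn = lon.ravel()[cand]
        order = np.lexsort((cn, -cl, dist), axis=-1)
        src = np.take_along_axis(cand, order, axis=-1)[:, 0]
        fill_src = (tgt_idx, src)
        r, c = spec.shape
        for m in range(12):
            flat = cube[m].ravel()
            flat[tgt_idx] = flat[src]
            fm = mask[m].ravel()
            fm[tgt_idx] = fm[src]

    ocean = ~paleo
    cube[:, ocean] = 0.0
    mask[:, ocean] = True

    prov = np.where(new_land, PROVENANCE_FILLED, PROVENANCE_ORIGINAL).astype(np.int16)
    prov_grid = GeoGrid(spec, prov, mask=ocean.copy(), units="dimensionless")
    stack = MonthlyStack.from_array(
        baseline.variable, spec, cube, mask, baseline.units
    )
    return stack, prov_grid


def mask_stack(stack: MonthlyStack, landmask: GeoGrid) -> MonthlyStack:
    """Set every non-land cell of all 12 months to nodata."""
    ocean = ~landmask.values.astype(bool)
    cube = stack.as_array().astype(float).copy()
    mask = stack.mask_array().copy()
    cube[:, ocean] = 0.0
    mask[:, ocean] = True
    return MonthlyStack.from_array(stack.variable, stack.spec, cube, mask, stack.units)
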