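"""Fidelity checks for downscaled products.

The central check aggregates a high-resolution product back to the
climate model's coarse grid (block mean) and correlates it with the raw
coarse paleo field, for each calibration method.  A faithful downscaling
should track the coarse simulation closely; the additive (raw
difference) calibration is expected to correlate better than the
ratio-of-anomalies one for precipitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import GeometryError, UndefinedCorrelationError
from .grid import GeoGrid, aggregate_mean


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length samples.

    Raises
    ------
    UndefinedCorrelationError
        For fewer than 3 pairs or zero variance in either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one argument")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class BoundingBox:
    """Inclusive lat/lon bounds selecting a sub-region of a grid."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def select(self, spec) -> np.ndarray:
        lat, lon = spec.center_mesh()
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )


@dataclass
class ComparisonReport:
    """Outcome of comparing both calibrations against the coarse truth."""

    pearson_raw: float
    pearson_roa: float
    range_raw: tuple[float, float]
    range_roa: tuple[float, float]
    n_pixels: int
    region: str = "global"
    undefined: tuple[str, ...] = ()

    def to_json(self) -> str:
        d = {
            "pearson_raw": self.pearson_raw,
            "pearson_roa": self.pearson_roa,
            "range_raw": list(self.range_raw),
            "range_roa": list(self.range_roa),
            "n_pixels": self.n_pixels,
            "region": self.region,
            "undefined": list(self.undefined),
        }
        return json.dumps(d)

    def to_text(self) -> str:
        lines = [
            f"region:      {self.region}",
            f"n_pixels:    {self.n_pixels}",
            f"pearson raw: {self.pearson_raw:.3f}",
            f"pearson roa: {self.pearson_roa:.3f}",
            f"range raw:   {self.range_raw[0]:.3f} .. {self.range_raw[1]:.3f}",
            f"range roa:   {self.range_roa[0]:.3f} .. {self.range_roa[1]:.3f}",
        ]
        if self.undefined:
            lines.append(f"undefined:   {', '.join(self.undefined)}")
        return "\n".join(lines)


def compare_methods(
    product_raw: GeoGrid,
    product_roa: GeoGrid,
    coarse_paleo: GeoGrid,
    region: BoundingBox | None = None,
) -> ComparisonReport:
    """Aggregate both fine products to the coarse grid and correlate.

    Each product is block-averaged to the coarse spec and correlated
    (Pearson, pairwise-complete) with the raw coarse paleo field over
    valid cells in ``region``.  A correlation that is undefined in the
    region (too few cells or zero variance) is reported as NaN and
    flagged in ``undefined`` rather than raised.
    """
    if product_raw.spec != product_roa.spec:
        raise GeometryError("the two products are on different grids")
    agg_raw = aggregate_mean(product_raw, coarse_paleo.spec)
    agg_roa = aggregate_mean(product_roa, coarse_paleo.spec)

    in_region = (
        region.select(coarse_paleo.spec)
        if region is not None
        else np.ones(coarse_paleo.spec.shape, dtype=bool)
    )
    region_name = (
        "global"
        if region is None
        else f"[{region.lat_min},{region.lat_max}]x[{region.lon_min},{region.lon_max}]"
    )

    undefined = []
    results = {}
    for name, agg in (("raw", agg_raw), ("roa", agg_roa)):
        ok = in_region & ~agg.mask & ~coarse_paleo.mask
        try:
            r = pearson(agg.values[ok], coarse_paleo.values[ok])
        except UndefinedCorrelationError:
            r = float("nan")
            undefined.append(f"pearson_{name}")
        results[name] = (r, int(ok.sum()))

    fine_region = (
        region.select(product_raw.spec)
        if region is not None
        else np.ones(product_raw.spec.shape, dtype=bool)
    )

    def fine_range(g: GeoGrid) -> tuple[float, float]:
        sel = fine_region & ~g.mask
        if not sel.any():
            return (float("nan"), float("nan"))
        v = g.values[sel]
        return (float(v.min()), float(v.max()))

    return ComparisonReport(
        pearson_raw=results["raw"][0],
        pearson_roa=results["roa"][0],
        range_raw=fine_range(product_raw),
        range_roa=fine_range(product_roa),
        n_pixels=results["raw"][1],
        region=region_name,
        undefined=tuple(undefined),
    )
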