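"""Derivation of the 19 bioclimatic variables from monthly climatologies.

The bioclimatic variables are the standard annual-summary, seasonality
and extreme/limiting descriptors used in species distribution modelling:

=====  ==========================================================
bio1   Annual mean temperature (°C×10)
bio2   Mean diurnal range, mean of monthly tmax − tmin (°C×10)
bio3   Isothermality, 100·bio2/bio7
bio4   Temperature seasonality, 100·sd of monthly tmean
bio5   Max temperature of warmest month (°C×10)
bio6   Min temperature of coldest month (°C×10)
bio7   Temperature annual range, bio5 − bio6 (°C×10)
bio8   Mean temperature of wettest quarter (°C×10)
bio9   Mean temperature of driest quarter (°C×10)
bio10  Mean temperature of warmest quarter (°C×10)
bio11  Mean temperature of coldest quarter (°C×10)
bio12  Annual precipitation (mm/year)
bio13  Precipitation of wettest month (mm/month)
bio14  Precipitation of driest month (mm/month)
bio15  Precipitation seasonality, coefficient of variation
bio16  Precipitation of wettest quarter (mm/quarter)
bio17  Precipitation of driest quarter (mm/quarter)
bio18  Precipitation of warmest quarter (mm/quarter)
bio19  Precipitation of coldest quarter (mm/quarter)
=====  ==========================================================

A quarter is any of the 12 circular windows of three consecutive months
(December wraps to January).  When tied, the window with the smallest
January-based start index wins.  When only mean temperature is
available, the five variables needing tmin/tmax (bio2, bio3, bio5,
bio6, bio7) are omitted, leaving 14.

Temperatures are delivered multiplied by 10 and rounded to integers
(half away from zero); precipitation layers are rounded to integer mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, GeometryError, UnitError
from .grid import GeoGrid, GridSpec, MonthlyStack

ALL_VARIABLES = tuple(f"bio{i}" for i in range(1, 20))
#: Variables that require monthly minimum and maximum temperature.
NEEDS_MINMAX = ("bio2", "bio3", "bio5", "bio6", "bio7")
#: Variables in temperature units, delivered as °C×10 integers.
TEMPERATURE_VARS = ("bio1", "bio2", "bio5", "bio6", "bio7", "bio8", "bio9", "bio10", "bio11")

_TEMP_UNIT_ALIASES = {"°C", "degC", "C", "celsius", "deg_C"}


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (so −2.55×10 → −26)."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x))


def encode_temperature(grid: GeoGrid) -> GeoGrid:
    """Encode a °C grid as integer tenths of a degree (int16)."""
    if grid.units not in _TEMP_UNIT_ALIASES:
        raise UnitError(f"expected temperature units (°C), got {grid.units!r}")
    enc = round_half_away(grid.values * 10.0).astype(np.int16)
    enc = np.where(grid.mask, np.int16(0), enc)
    return GeoGrid(grid.spec, enc, grid.mask.copy(), units="°C*10")


def _seq_sum(cube: np.ndarray) -> np.ndarray:
    """Sequential (month 1 → 12) summation along the first axis.

    Fixes the floating-point reduction order so results are identical to
    a straight-line per-pixel loop, independent of array layout.
    """
    out = cube[0].astype(float).copy()
    for m in range(1, cube.shape[0]):
        out = out + cube[m]
    return out


def _seq_std(cube: np.ndarray, ddof: int) -> np.ndarray:
    n = cube.shape[0]
    mu = _seq_sum(cube) / n
    var = _seq_sum((cube - mu) ** 2) / (n - ddof)
    return np.sqrt(var)


def quarter_windows() -> list[tuple[int, int, int]]:
    """The 12 circular three-month windows, January-based start index."""
    return [(k, (k + 1) % 12, (k + 2) % 12) for k in range(12)]


def quarter_sums_and_means(tmean, prec):
    """Three-month circular window sums of precip and means of temperature.

    Accepts 12-vectors or (12, ...) arrays; returns (sums, means), each
    with a leading window axis of length 12 where window k covers months
    k, k+1, k+2 modulo 12.
    """
    t = np.asarray(tmean, dtype=float)
    p = np.asarray(prec, dtype=float)
    if t.shape[0] != 12 or p.shape[0] != 12:
        raise ValueError("need 12 monthly values along the first axis")
    idx = np.array(quarter_windows())  # (12, 3)
    psum = (p[idx[:, 0]] + p[idx[:, 1]]) + p[idx[:, 2]]
    tmeanq = ((t[idx[:, 0]] + t[idx[:, 1]]) + t[idx[:, 2]]) / 3.0
    return psum, tmeanq


def bioclim_values(
    tmean,
    prec,
    tmin=None,
    tmax=None,
    ddof: int = 1,
) -> dict[str, np.ndarray]:
    """All available bioclim values, unencoded, from (12, ...) arrays.

    Temperatures in °C, precipitation in mm/month.  Returns float arrays
    (one per variable) in natural units: temperature variables in °C,
    bio4 already ×100, bio3 and bio15 as percentages.  ``ddof=1`` uses
    the sample standard deviation.
    """
    t = np.asarray(tmean, dtype=float)
    p = np.asarray(prec, dtype=float)
    if (tmin is None) != (tmax is None):
        raise ConfigurationError("tmin and tmax must both be given or both omitted")
    have_minmax = tmin is not None

    out: dict[str, np.ndarray] = {}
    out["bio1"] = _seq_sum(t) / 12.0
    out["bio4"] = 100.0 * _seq_std(t, ddof)
    out["bio12"] = _seq_sum(p)
    out["bio13"] = p.max(axis=0)
    out["bio14"] = p.min(axis=0)
    out["bio15"] = 100.0 * _seq_std(p, ddof) / (1.0 + out["bio12"] / 12.0)

    psum, tq = quarter_sums_and_means(t, p)
    wettest = psum.argmax(axis=0)
    driest = psum.argmin(axis=0)
    warmest = tq.argmax(axis=0)
    coldest = tq.argmin(axis=0)

    def pick(cube, which):
        return np.take_along_axis(cube, which[None, ...], axis=0)[0]

    out["bio8"] = pick(tq, wettest)
    out["bio9"] = pick(tq, driest)
    out["bio10"] = pick(tq, warmest)
    out["bio11"] = pick(tq, coldest)
    out["bio16"] = pick(psum, wettest)
    out["bio17"] = pick(psum, driest)
    out["bio18"] = pick(psum, warmest)
    out["bio19"] = pick(psum, coldest)

    if have_minmax:
        tn = np.asarray(tmin, dtype=float)
        tx = np.asarray(tmax, dtype=float)
        out["bio2"] = _seq_sum(tx - tn) / 12.0
        out["bio5"] = tx.max(axis=0)
        out["bio6"] = tn.min(axis=0)
        out["bio7"] = out["bio5"] - out["bio6"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out["bio3"] = np.where(
                out["bio7"] == 0, 0.0, 100.0 * out["bio2"] / out["bio7"]
            )
    return out


@dataclass
class BioclimSet:
    """Encoded bioclim layers keyed ``bio1`` ... ``bio19``.

    ``available`` lists the variables actually computed: all 19 when
    tmin/tmax were supplied, otherwise the 14 that need only mean
    temperature.  Temperature-unit layers are int16 °C×10; precipitation
    layers int32 mm.
    """

    layers: Mapping[str, GeoGrid]
    available: tuple[str, ...]

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.layers.values())).spec

    def __getitem__(self, name: str) -> GeoGrid:
        return self.layers[name]


def compute_bioclim(
    tmean: MonthlyStack,
    precip: MonthlyStack,
    tmin: MonthlyStack | None = None,
    tmax: MonthlyStack | None = None,
    *,
    quantize_input: bool = True,
    ddof: int = 1,
) -> BioclimSet:
    """Derive the bioclimatic variables from monthly stacks.

    With ``quantize_input`` (default) the monthly temperatures are first
    rounded to 0.1 °C, mirroring a pipeline whose monthly products are
    stored as °C×10 integers before derivation; set False to derive from
    full-precision floats.  Nodata propagates per pixel (union over all
    input months).
    """
    if (tmin is None) != (tmax is None):
        raise ConfigurationError("tmin and tmax must both be given or both omitted")
    stacks = [s for s in (tmean, precip, tmin, tmax) if s is not None]
    spec = tmean.spec
    for s in stacks:
        if s.spec != spec:
            raise GeometryError(f"{s.variable} stack is on a different grid")

    def temps(stack):
        a = stack.as_array().astype(float)
        return round_half_away(a * 10.0) / 10.0 if quantize_input else a

    t = temps(tmean)
    p = precip.as_array().astype(float)
    tn = temps(tmin) if tmin is not None else None
    tx = temps(tmax) if tmax is not None else None

    mask = np.zeros(spec.shape, dtype=bool)
    for s in stacks:
        mask |= s.mask_array().any(axis=0)

    vals = bioclim_values(t, p, tn, tx, ddof=ddof)

    layers: dict[str, GeoGrid] = {}
    for name in ALL_VARIABLES:
        if name not in vals:
            continue
        v = vals[name]
        if name in TEMPERATURE_VARS:
            enc = round_half_away(v * 10.0).astype(np.int16)
            units = "°C*10"
        else:
            enc = round_half_away(v).astype(np.int32)
            units = "mm" if name in ("bio12", "bio13", "bio14", "bio16", "bio17", "bio18", "bio19") else "dimensionless"
        enc = np.where(mask, 0, enc).astype(enc.dtype)
        layers[name] = GeoGrid(spec, enc, mask.copy(), units=units)

    available = tuple(n for n in ALL_VARIABLES if n in layers)
    return BioclimSet(layers=layers, available=available)
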