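"""Change-factor (delta) calibration between paleo and control climatologies.

The change-factor method measures, at the climate model's native
resolution, how a paleo climatology differs from the model's own
pre-industrial control run, and imposes that anomaly on a high-resolution
modern baseline.  Two calibrations are supported:

``raw``
    Additive anomaly: delta = paleo − control; recombined as
    baseline + delta.  Valid for temperature and precipitation.
``roa``
    Ratio of anomalies: factor = paleo / control; recombined as
    baseline × factor.  Only meaningful for precipitation, and known to
    inflate wet gradients and freeze zero-rainfall pixels at zero.

After recombination, negative precipitation is clamped to zero;
temperature is never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError
from .grid import GeoGrid, GridSpec, MonthlyStack

METHODS = ("raw", "roa")


def _check_method(method: str, variable: str) -> None:
    if method not in METHODS:
        raise ConfigurationError(f"unknown calibration method {method!r}; one of {METHODS}")
    if method == "roa" and variable != "precip":
        raise ConfigurationError(
            "ratio-of-anomalies calibration is only defined for precipitation, "
            f"not {variable!r}"
        )


@dataclass
class DeltaField:
    """Per-month calibration layers for one variable.

    ``months`` holds 12 GeoGrids on one spec: differences in the
    variable's units for the raw method, dimensionless ratios for roa.
    ``zero_control_pixels`` counts valid pixels where the roa ratio was
    undefined (control = 0) and was therefore marked nodata.
    """

    variable: str
    method: str
    months: Sequence[GeoGrid]
    zero_control_pixels: int = 0

    def __post_init__(self) -> None:
        _check_method(self.method, self.variable)
        self.months = list(self.months)
        if len(self.months) != 12:
            raise GeometryError(f"a DeltaField needs 12 layers, got {len(self.months)}")
        spec = self.months[0].spec
        for m, g in enumerate(self.months):
            if g.spec != spec:
                raise GeometryError(f"delta month {m + 1} is on a different grid")

    @property
    def spec(self) -> GridSpec:
        return self.months[0].spec


def compute_delta(
    paleo: MonthlyStack, control: MonthlyStack, method: str = "raw"
) -> DeltaField:
    """Month-wise calibration layers between paleo and control stacks.

    raw: paleo − control.  roa: paleo / control (precipitation only);
    valid pixels where control = 0 are set nodata and counted in the
    returned field's ``zero_control_pixels``.
    """
    if paleo.variable != control.variable:
        raise GeometryError(
            f"variable mismatch: {paleo.variable!r} vs {control.variable!r}"
        )
    if paleo.spec != control.spec:
        raise GeometryError("paleo and control stacks are on different grids")
    _check_method(method, paleo.variable)

    p = paleo.as_array().astype(float)
    c = control.as_array().astype(float)
    mask = paleo.mask_array() | control.mask_array()
    n_zero = 0
    if method == "raw":
        vals = p - c
        units = paleo.units
    else:
        zero = (~mask) & (c == 0)
        n_zero = int(zero.sum())
        mask = mask | zero
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(mask, 0.0, p / np.where(c == 0, 1.0, c))
        units = ""
    months = [
        GeoGrid(paleo.spec, vals[m], mask[m], units) for m in range(12)
    ]
    return DeltaField(paleo.variable, method, months, zero_control_pixels=n_zero)


def apply_delta(baseline: MonthlyStack, delta: DeltaField) -> MonthlyStack:
    """Recombine a (downscaled) delta field with a high-resolution baseline.

    raw deltas are added, roa factors multiplied, month by month.
    Precipitation output is clamped at zero from below; temperature is
    left untouched.  Nodata is the union of both inputs' masks.
    """
    if baseline.variable != delta.variable:
        raise GeometryError(
            f"variable mismatch: baseline {baseline.variable!r} vs delta {delta.variable!r}"
        )
    if baseline.spec != delta.spec:
        raise GeometryError("baseline and delta are on different grids")

    b = baseline.as_array().astype(float)
    d = np.stack([g.values for g in delta.months]).astype(float)
    mask = baseline.mask_array() | np.stack([g.mask for g in delta.months])
    out = b + d if delta.method == "raw" else b * d
    if baseline.variable == "precip":
        out = np.maximum(out, 0.0)
    out = np.where(mask, 0.0, out)
    return MonthlyStack.from_array(
        baseline.variable, baseline.spec, out, mask, baseline.units
    )
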