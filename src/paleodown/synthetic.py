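"""Synthetic inputs with known ground truth for exercising the pipeline.

Real runs consume a coarse GCM paleo/control pair, a high-resolution
modern baseline climatology and a bathymetry grid.  This module builds
all of them from closed-form smooth fields so that every downstream
quantity has a known answer: the control climatology is a sum of at most
three low-frequency sinusoids with a month-varying phase, the paleo run
is the control plus a prescribed additive (or multiplicative) anomaly,
and the baseline is the same smooth field sampled on the fine grid plus
a high-frequency "topographic" term and seeded Gaussian noise.  The
bathymetry ramps across the domain from −80 m to +80 m so that both a
+25 m and a −40 m sea-level scenario visibly move the coastline.

Also provided is the single-number worked example used throughout the
documentation: paleo rainfall 2.0 m/mo vs control 1.0 m/mo applied to a
baseline spanning 0.25–4.0 m/mo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GeoGrid, GridSpec, MonthlyStack

#: Default coarse window: 10 × 10 cells of 2.5°, i.e. a 25° × 25° region.
DEFAULT_COARSE = GridSpec(
    lat_origin=25.0, lon_origin=0.0,
    cell_size_lat=2.5, cell_size_lon=2.5,
    n_rows=10, n_cols=10,
)
#: Default fine grid: the same window at 2.5 arc-minutes (60× refinement).
DEFAULT_FINE = DEFAULT_COARSE.refine(60)


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the synthetic world.

    ``anomaly_amplitude`` is in the variable's units for additive
    anomalies (mm/month here) and a relative excess for multiplicative
    ones (0.5 → factors up to 1.5).  ``topo_amplitude`` and ``noise_sd``
    control the fine-scale structure the coarse model cannot see.
    ``bias_amplitude`` sets the smooth discrepancy between the modern
    baseline climatology and the model's control run — GCM control runs
    are systematically biased against observations, which is why the
    change-factor method exists at all, and which is what the two
    calibrations propagate differently (additively vs multiplied by the
    spatially varying anomaly ratio).
    """

    seed: int = 0
    coarse_spec: GridSpec = DEFAULT_COARSE
    fine_spec: GridSpec = DEFAULT_FINE
    anomaly_kind: str = "additive"
    anomaly_amplitude: float = 50.0
    topo_amplitude: float = 5.0
    noise_sd: float = 2.0
    bias_amplitude: float = 8.0

    def __post_init__(self) -> None:
        if self.anomaly_kind not in ("additive", "multiplicative"):
            raise ValueError(f"unknown anomaly kind {self.anomaly_kind!r}")
        if min(self.anomaly_amplitude, self.topo_amplitude,
               self.noise_sd, self.bias_amplitude) < 0:
            raise ValueError("amplitudes must be nonnegative")


def _control_field(lat, lon, month: int, variable: str) -> np.ndarray:
    """Smooth low-frequency climatology: ≤3 sinusoids, month-varying phase."""
    phase = 2.0 * np.pi * month / 12.0
    if variable == "precip":
        return (
            100.0
            + 40.0 * np.sin(2.0 * np.pi * lat / 50.0 + phase)
            + 30.0 * np.cos(2.0 * np.pi * lon / 50.0)
            + 20.0 * np.sin(2.0 * np.pi * (lat + lon) / 60.0 + phase)
        )
    return (
        15.0
        + 8.0 * np.sin(2.0 * np.pi * lat / 50.0 + phase)
        + 5.0 * np.cos(2.0 * np.pi * lon / 50.0)
        + 3.0 * np.sin(2.0 * np.pi * (lat + lon) / 60.0 + phase)
    )


def anomaly_field(lat, lon, params: FixtureParams) -> np.ndarray:
    """The prescribed anomaly: additive offset or multiplicative factor."""
    shape = 0.5 + 0.5 * np.sin(np.pi * lat / 25.0) * np.cos(np.pi * lon / 25.0)
    if params.anomaly_kind == "additive":
        return params.anomaly_amplitude * shape
    return 1.0 + params.anomaly_amplitude * shape


def make_climatology_pair(
    params: FixtureParams, variable: str = "precip"
) -> tuple[MonthlyStack, MonthlyStack]:
    """Coarse (paleo, control) stacks with a known anomaly between them."""
    spec = params.coarse_spec
    lat, lon = spec.center_mesh()
    units = "mm/month" if variable == "precip" else "°C"
    control_cube = np.stack(
        [_control_field(lat, lon, m, variable) for m in range(12)]
    )
    anom = anomaly_field(lat, lon, params)
    if params.anomaly_kind == "additive":
        paleo_cube = control_cube + anom
    else:
        paleo_cube = control_cube * anom
    if variable == "precip":
        control_cube = np.maximum(control_cube, 0.0)
        paleo_cube = np.maximum(paleo_cube, 0.0)
    control = MonthlyStack.from_array(variable, spec, control_cube, units=units)
    paleo = MonthlyStack.from_array(variable, spec, paleo_cube, units=units)
    return paleo, control


def make_fine_baseline(
    params: FixtureParams, variable: str = "precip"
) -> tuple[MonthlyStack, GeoGrid]:
    """High-resolution baseline with topographic texture, plus bathymetry.

    The baseline equals the control climatology evaluated at the fine
    cell centres, plus a smooth observational-bias field of amplitude
    ``bias_amplitude`` (different wavelength and phase from the control,
    emulating the systematic discrepancy between a GCM control run and
    the observed modern climatology), plus ``topo_amplitude`` of
    ~1°-wavelength structure and Gaussian noise with sd ``noise_sd``
    (seeded).  The bathymetry is
    a west-to-east ramp from −80 m to +80 m with a gentle latitudinal
    ripple, so the −60…+60 m band around the modern coast is populated.
    """
    spec = params.fine_spec
    lat, lon = spec.center_mesh()
    units = "mm/month" if variable == "precip" else "°C"
    rng = np.random.default_rng(params.seed)
    topo = params.topo_amplitude * np.sin(2.0 * np.pi * lat) * np.cos(2.0 * np.pi * lon)
    bias = params.bias_amplitude * np.sin(
        2.0 * np.pi * lat / 35.0 + 1.0
    ) * np.cos(2.0 * np.pi * lon / 35.0 + 0.5)
    cube = np.stack(
        [
            _control_field(lat, lon, m, variable)
            + bias
            + topo
            + (
                rng.normal(0.0, params.noise_sd, size=spec.shape)
                if params.noise_sd > 0
                else 0.0
            )
            for m in range(12)
        ]
    )
    if variable == "precip":
        cube = np.maximum(cube, 0.0)
    baseline = MonthlyStack.from_array(variable, spec, cube, units=units)

    lon_w = spec.lon_origin
    lon_e = spec.lon_origin + spec.n_cols * spec.cell_size_lon
    frac = (lon - lon_w) / (lon_e - lon_w)
    elevation = -80.0 + 160.0 * frac + 6.0 * np.sin(2.0 * np.pi * lat / 10.0)
    bathymetry = GeoGrid(spec, elevation, units="m")
    return baseline, bathymetry


@dataclass
class WorkedExample:
    """The single-location rainfall example: 2.0 vs 1.0 m/mo on 0.25–4.0."""

    paleo: MonthlyStack
    control: MonthlyStack
    baseline: MonthlyStack
    coarse_spec: GridSpec
    fine_spec: GridSpec


def worked_example_fixture(refine: int = 15) -> WorkedExample:
    """Uniform paleo 2.0 m/mo and control 1.0 m/mo over a small window,
    with a fine baseline spanning exactly 0.25–4.0 m/mo.

    The raw calibration gives a delta of +1.0 m/mo and an output range
    of 1.25–5.0 m/mo; the ratio-of-anomalies calibration gives a factor
    of 2 and a range of 0.5–8.0 m/mo.
    """
    coarse = GridSpec(
        lat_origin=5.0, lon_origin=0.0,
        cell_size_lat=2.5, cell_size_lon=2.5,
        n_rows=4, n_cols=4,
    )
    fine = coarse.refine(refine)
    units = "m/month"
    paleo = MonthlyStack.from_array(
        "precip", coarse, np.full((12, 4, 4), 2.0), units=units
    )
    control = MonthlyStack.from_array(
        "precip", coarse, np.full((12, 4, 4), 1.0), units=units
    )
    n = fine.n_rows * fine.n_cols
    ramp = np.linspace(0.25, 4.0, n).reshape(fine.shape)
    baseline = MonthlyStack.from_array(
        "precip", fine, np.stack([ramp] * 12), units=units
    )
    return WorkedExample(paleo, control, baseline, coarse, fine)
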