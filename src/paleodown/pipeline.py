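"""End-to-end orchestration of the downscaling sequence.

Stage order, which tests pin down because it is scientifically
meaningful, is:

1. ``compute_delta`` — calibrate paleo against control at coarse scale;
2. ``downscale_field`` — tension-spline the 12 delta layers to the fine grid;
3. ``apply_delta`` — recombine with the baseline (negative precipitation
   clamped to zero here);
4. sea-level adjustment — paleo landmask from bathymetry, nearest-land
   fill of newly exposed shelf, ocean set to nodata;
5. ``encode_temperature`` — monthly temperatures to °C×10 integers;
6. ``compute_bioclim`` — derive the bioclimatic variables from the
   masked monthly products.

``run_pipeline`` works on in-memory stacks and returns everything;
``run_pipeline_files`` wraps it with raster I/O and writes a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .bioclim import BioclimSet, compute_bioclim, encode_temperature
from .change_factor import DeltaField, apply_delta, compute_delta
from .errors import PaleodownError
from .grid import GeoGrid, MonthlyStack
from .io import read_geotiff, read_monthly_geotiffs, read_netcdf_stack, write_geotiff, write_monthly_geotiffs
from .sea_level import SeaLevelScenario, extend_baseline_to_new_land, paleo_landmask
from .spline import SplineParams, downscale_field, make_downscale_plan

logger = logging.getLogger(__name__)


class StageError(PaleodownError):
    """A pipeline stage failed; the message names the stage and layer."""


@dataclass
class PipelineResult:
    """Everything a pipeline run produces, in memory."""

    monthly: dict[str, MonthlyStack]
    deltas: dict[str, DeltaField]
    bioclim: BioclimSet | None
    provenance: GeoGrid | None
    manifest: dict


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PaleodownError as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(
    paleo: Mapping[str, MonthlyStack],
    control: Mapping[str, MonthlyStack],
    baseline: Mapping[str, MonthlyStack],
    bathymetry: GeoGrid | None = None,
    *,
    precip_method: str = "raw",
    spline: SplineParams = SplineParams(),
    scenario: SeaLevelScenario = SeaLevelScenario(0.0),
    encode_temps: bool = True,
    mask_before_bioclim: bool = True,
    derive_bioclim: bool = True,
) -> PipelineResult:
    """Run calibration → downscaling → recombination → masking → bioclim.

    ``paleo``, ``control`` and ``baseline`` map variable names
    (``tmean``, ``precip``, optionally ``tmin``/``tmax``) to stacks.
    Temperature is always calibrated with raw differences;
    ``precip_method`` chooses ``raw`` or ``roa`` for precipitation.
    Without a bathymetry grid the sea-level stage is skipped.
    """
    variables = sorted(paleo)
    if sorted(control) != variables or set(baseline) < set(variables):
        raise StageError(
            "stage 'validate-config' failed: paleo/control/baseline variables differ"
        )
    fine_spec = next(iter(baseline.values())).spec

    monthly: dict[str, MonthlyStack] = {}
    deltas: dict[str, DeltaField] = {}
    plans: dict[bytes, object] = {}
    provenance = None

    for var in variables:
        method = precip_method if var == "precip" else "raw"
        delta = _stage(
            f"compute_delta[{var}]", compute_delta, paleo[var], control[var], method
        )
        if delta.zero_control_pixels:
            logger.warning(
                "%s: %d zero-control pixels set nodata in roa delta",
                var, delta.zero_control_pixels,
            )
        fine_months = []
        for m, layer in enumerate(delta.months):
            key = layer.mask.tobytes()
            if key not in plans:
                plans[key] = _stage(
                    f"downscale-plan[{var}, month {m + 1}]",
                    make_downscale_plan, layer.spec, ~layer.mask, fine_spec, spline,
                )
            fine_months.append(
                _stage(
                    f"downscale[{var}, month {m + 1}]",
                    downscale_field, layer, fine_spec, spline, plans[key],
                )
            )
        delta_fine = DeltaField(var, method, fine_months, delta.zero_control_pixels)
        deltas[var] = delta
        product = _stage(
            f"apply_delta[{var}]", apply_delta, baseline[var], delta_fine
        )
        monthly[var] = product

    unmasked = dict(monthly)
    paleo_ocean = None
    if bathymetry is not None:
        modern = _stage(
            "landmask[modern]", paleo_landmask, bathymetry, SeaLevelScenario(0.0)
        )
        paleo_mask = _stage(
            "landmask[paleo]", paleo_landmask, bathymetry, scenario
        )
        paleo_ocean = ~paleo_mask.values.astype(bool)
        for var in variables:
            monthly[var], provenance = _stage(
                f"sea_level[{var}]",
                extend_baseline_to_new_land, monthly[var], modern, paleo_mask,
            )

    bioclim = None
    if derive_bioclim and "tmean" in monthly and "precip" in monthly:
        src = monthly if mask_before_bioclim else unmasked
        bioclim = _stage(
            "bioclim",
            compute_bioclim,
            src["tmean"],
            src["precip"],
            src.get("tmin"),
            src.get("tmax"),
            quantize_input=encode_temps,
        )
        if not mask_before_bioclim and paleo_ocean is not None:
            for name in bioclim.available:
                g = bioclim.layers[name]
                g.mask |= paleo_ocean
                g.values = np.where(g.mask, 0, g.values).astype(g.values.dtype)

    if encode_temps:
        for var in variables:
            if var != "precip":
                monthly[var] = MonthlyStack(
                    var,
                    [
                        _stage(f"encode[{var}, month {m + 1}]", encode_temperature, g)
                        for m, g in enumerate(monthly[var].months)
                    ],
                )

    manifest = {
        "version": __version__,
        "variables": variables,
        "precip_method": precip_method,
        "spline": {"tension": spline.tension, "n_neighbors": spline.n_neighbors},
        "sea_level_offset_m": scenario.offset_m if bathymetry is not None else None,
        "encode_temps": encode_temps,
        "mask_before_bioclim": mask_before_bioclim,
        "fine_shape": list(fine_spec.shape),
    }
    return PipelineResult(monthly, deltas, bioclim, provenance, manifest)


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (paths + parameters)."""

    paleo: str
    control: str
    baseline: str
    out: str
    bathymetry: str | None = None
    variables: tuple[str, ...] = ("tmean", "precip")
    precip_method: str = "raw"
    tension: float = 0.1
    n_neighbors: int = 12
    sea_level_m: float = 0.0
    encode_temps: bool = True
    mask_before_bioclim: bool = True


def _read_stack(path: str, variable: str) -> MonthlyStack:
    p = Path(path)
    if p.suffix == ".nc":
        return read_netcdf_stack(p, variable)
    return read_monthly_geotiffs(p, variable)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline_files(config: PipelineConfig) -> Path:
    """Read inputs, run the pipeline, write GeoTIFFs and a manifest.

    Outputs land in ``config.out``: ``<var>_01.tif`` … ``<var>_12.tif``
    per variable, ``bio_1.tif`` … ``bio_19.tif``, a ``provenance.tif``
    when sea level moved, and ``manifest.jsonl``.
    """
    paleo = {v: _read_stack(config.paleo, v) for v in config.variables}
    control = {v: _read_stack(config.control, v) for v in config.variables}
    baseline = {v: _read_stack(config.baseline, v) for v in config.variables}
    bathymetry = read_geotiff(config.bathymetry) if config.bathymetry else None

    result = run_pipeline(
        paleo, control, baseline, bathymetry,
        precip_method=config.precip_method,
        spline=SplineParams(config.tension, config.n_neighbors),
        scenario=SeaLevelScenario(config.sea_level_m),
        encode_temps=config.encode_temps,
        mask_before_bioclim=config.mask_before_bioclim,
    )

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for var, stack in result.monthly.items():
        written += write_monthly_geotiffs(stack, out, prefix=var)
    if result.bioclim is not None:
        for name in result.bioclim.available:
            idx = name[3:]
            written.append(
                write_geotiff(result.bioclim[name], out / f"bio_{idx}.tif")
            )
    if result.provenance is not None:
        written.append(write_geotiff(result.provenance, out / "provenance.tif"))

    manifest = dict(result.manifest)
    manifest["inputs"] = {
        name: _checksum_tree(Path(p))
        for name, p in (
            ("paleo", config.paleo),
            ("control", config.control),
            ("baseline", config.baseline),
            ("bathymetry", config.bathymetry),
        )
        if p
    }
    manifest_path = out / "manifest.jsonl"
    with open(manifest_path, "w") as fh:
        fh.write(json.dumps(manifest, sort_keys=True) + "\n")
        for path in written:
            fh.write(
                json.dumps({"output": path.name, "sha256": _sha256(path)}) + "\n"
            )
    return out


def _checksum_tree(path: Path) -> dict:
    if path.is_file():
        return {path.name: _sha256(path)}
    return {f.name: _sha256(f) for f in sorted(path.glob("*")) if f.is_file()}
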