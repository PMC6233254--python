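# Methods

This note documents the models, parameter choices and numerical
behaviour of `paleodown`, and what the synthetic test world does and
does not establish about real data.

## Grids and rasters

All rasters are regular latitude/longitude grids in the WGS84 geographic
CRS. Row 0 is the northernmost row, coordinates refer to cell centers
(`edge + (index + 0.5)·cell_size`), and intervals are half-open on their
south/east edges. Nodata is carried as an explicit boolean mask in
memory and serialized as a sentinel recorded in the GDAL nodata tag
(−9999 for float rasters, the type minimum for int16/int32). GeoTIFF
I/O is implemented directly on the TIFF geo-tags (pixel scale, tiepoint,
geokey directory); CF-style NetCDF-3 is accepted for coarse GCM
climatologies, with south-to-north files flipped on read. Both read
paths yield identical in-memory semantics.

Block aggregation to a coarser grid (`aggregate_mean`) requires an
integer cell-size ratio and coincident origins, and uses the unweighted
arithmetic mean of valid fine cells per block; within a 2.5° cell the
latitude variation of cell areas is negligible, so no area weighting is
applied. A block with no valid fine cell becomes nodata.

## Change-factor calibration

The anomaly between a paleo climatology and the model's pre-industrial
control is computed month-wise per pixel, either as a raw difference
(`paleo − control`, any variable) or as a ratio of anomalies
(`paleo / control`, precipitation only — a ratio of temperatures in °C
is physically meaningless, so the ratio method is rejected for
temperature as a precondition). A valid pixel whose control
precipitation is exactly zero has an undefined ratio; it is marked
nodata and counted in the delta field's diagnostics rather than given a
fabricated capped value. Ratios are interpolated in ratio space (not
log-ratio space): that is the literal reading of "ratio of anomalies",
though log-space interpolation would guarantee positive downscaled
factors; downscaled ratios that interpolate slightly below zero would
surface in the recombined product through the precipitation clamp.

Recombination adds raw deltas to, or multiplies ratio factors with, the
high-resolution baseline. Negative precipitation is clamped to zero
*after* delta application and *before* sea-level masking and integer
encoding; temperature is never clamped. The output nodata mask is the
union of the baseline's and the (downscaled) delta's masks.

## Spline with tension

The named GIS "tensioned spline" tools implement the classical
spline-with-tension radial basis; that documented mathematics is
implemented here directly so results are reproducible and testable:

    R(r) = −(1 / 2πφ²)·[ ln(φr/2) + γ + K₀(φr) ],  R(0) = 0.

For each fine cell center the `n_neighbors` (default 12) nearest valid
coarse cell centers are found and the (N+1)-point symmetric system
`[R_ij 1; 1ᵀ 0]·[λ; a] = [z; 0]` is solved, giving an interpolant that
passes exactly through the samples with weights summing to zero.
Whether the original tools' "weight" parameter maps exactly onto φ in
this basis is not determinable; φ is therefore an explicit, documented
parameter defaulting to 0.1.

Numerical and determinism choices:

- **Distance metric**: great-circle arc length expressed in degrees,
  with longitude treated periodically (antimeridian-safe). Planar degree
  distance would distort neighborhoods near the poles. Neighbor queries
  use a k-d tree on unit vectors (chord distance is monotone in arc
  length, so the ordering is exact).
- **Tie-breaking**: neighbor ties are resolved by (distance, latitude
  descending, longitude ascending). A few extra candidates are queried
  so that exact ties at the cut-off rank resolve identically on every
  run. There is no randomness anywhere in the module.
- **Linear algebra**: LAPACK partial-pivoting solves. The single-fit
  path logs a warning when the system's condition number exceeds 1e10;
  the batched downscaling path raises on singular systems.
- **Plan reuse**: the neighbor search, the grouping of fine cells by
  neighbor set and the assembled local systems depend only on the grids,
  the coarse nodata mask and the parameters, so one `DownscalePlan` is
  shared across the 12 months (and variables) of a run. Results are
  bit-identical to per-layer planless execution (tested).

At a 60-fold refinement every coarse value is reproduced at its own
node to ~1e-12 relative error, constant fields are reproduced exactly
everywhere, and aggregating a downscaled smooth field back to the coarse
grid correlates with the original above r = 0.99.

## Sea-level coastline adjustment

A cell is paleo land exactly when its modern elevation (metres relative
to modern sea level, negative below) exceeds the period's sea-level
offset (+25 m mid-Pliocene Warm Period, −40 m M2 glacial, 0 m MIS19).
Land area is therefore non-increasing in the offset. Cells that are
land only under the paleo mask (exposed shelf) take the values of the
nearest modern-land cell — the most conservative extension available,
since no modern observations exist there — and are flagged `1` in a
provenance band (`0` = original land, nodata = ocean) so users can
exclude them. Monthly layers are masked before bioclim derivation, so
quarter statistics never mix land and filled/ocean values; the pipeline
flag `mask_before_bioclim=False` switches to deriving first and masking
the bioclim layers afterwards.

## Bioclimatic variables

A quarter is any of the 12 circular windows of three consecutive months
(December wraps to January). Wettest/driest quarters maximize/minimize
the three-month precipitation sum; warmest/coldest the three-month mean
temperature. Ties go to the window with the smallest January-based
start index — deterministic and consistent with common implementations,
though no published tie rule exists to compare against.

Choices that a formula sheet would not pin down:

- **Standard deviation** (bio4, bio15) uses the sample (n−1) form,
  matching the widely used reference implementations; `ddof` is a
  parameter.
- **bio15** divides by `1 + bio12/12` so arid pixels with near-zero
  annual precipitation do not blow up the coefficient of variation.
- **bio3** (isothermality) is reported ×100, as a percentage; where the
  annual range bio7 is zero, bio3 is defined as 0.
- **Encoding**: temperatures ×10, rounded half away from zero, int16;
  precipitation totals rounded to integer mm, int32. By default the
  monthly temperatures are first quantized to 0.1 °C before derivation,
  mirroring a pipeline whose monthly products are stored as ×10
  integers; `quantize_input=False` derives from full-precision floats.
- **Reduction order**: monthly sums/means/deviations accumulate
  sequentially January → December, so a per-pixel straight-line
  reference reproduces the vectorized results to 1 ulp.

When tmin/tmax are absent the five variables requiring them (bio2, bio3,
bio5, bio6, bio7) are omitted and exactly 14 layers are produced.

## Synthetic world

The generator builds every input the pipeline needs from closed-form
fields, fully determined by a seed:

- **Control climatology**: sums of at most three low-frequency sinusoids
  in lat/lon with a month-varying phase; precipitation means ~100
  mm/month, never below ~10, temperatures ~15 ± 16 °C.
- **Anomaly**: a prescribed smooth field, additive (default amplitude
  50 mm/month) or multiplicative, so the ground-truth delta is known
  exactly at every coarse node.
- **Baseline**: the control field sampled at fine resolution, plus a
  smooth observational-bias field (default 8 mm/month, ~8 % of the mean
  — representative of GCM precipitation biases against observed
  climatologies), plus ~1°-wavelength "topographic" texture (default
  5 mm/month) and seeded Gaussian noise (default sd 2 mm/month). The
  bias term matters: it is the baseline-vs-control discrepancy that the
  two calibrations propagate differently (an additive anomaly shifts it
  unchanged; a ratio modulates it by the spatially varying anomaly
  factor), which is why the additive method correlates better with the
  coarse truth after aggregation.
- **Bathymetry**: a west-to-east ramp from −80 m to +80 m with a gentle
  latitudinal ripple, so sea-level offsets of +25 m and −40 m both move
  the coastline substantially.
- Default problem size: 10×10 coarse cells of 2.5° and the same window
  at 2.5 arc-minutes (600×600), preserving the 60× refinement while the
  full two-variable pipeline runs in seconds.

What passing on this world shows: the calibration algebra, the exact
interpolation property, clamping, mask logic, encoding and the
qualitative superiority of the additive calibration are all correct.
What it does not show: skill on real climate — the fields have no
monsoon dynamics, no orographic rain shadows, no correlated noise, and
the published correlation values against real GCM/baseline rasters
cannot be reproduced without those datasets.

## Pipeline

Stage order is fixed and pinned by tests: calibrate → downscale →
recombine (clamp) → sea-level mask/fill → encode → bioclim. Any stage
failure aborts with the stage name and offending layer/month. No stage
mutates inputs on disk; the run manifest (JSON lines) records every
parameter and input/output checksum and contains no timestamps, so
identical configurations give byte-identical outputs.

## Known limitations

- No reprojection; all inputs must already be WGS84 geographic regular
  grids. Curvilinear GCM grids must be regridded upstream.
- The tension-spline neighborhood (k = 12) makes the interpolant
  piecewise; across neighbor-set boundaries the surface can have small
  discontinuities, as in the original locally-fitted tools.
- Ratio deltas are interpolated in ratio space; strongly varying ratios
  near zero-control pixels can interpolate below zero before the clamp.
- Nearest-neighbor shelf filling ignores elevation lapse rates; filled
  cells should be treated as low-confidence (see the provenance band).
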