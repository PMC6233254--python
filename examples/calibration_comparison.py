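"""Compare the two precipitation calibrations against the coarse truth.

Downscales the same synthetic paleo anomaly with raw differences and
with ratios of anomalies, aggregates both products back to the climate
model's grid, and correlates each with the raw paleo field — the
fidelity check that favours the additive method.
"""

import numpy as np

from paleodown import (
    DeltaField,
    FixtureParams,
    apply_delta,
    compare_methods,
    compute_delta,
    downscale_field,
    make_climatology_pair,
    make_fine_baseline,
)
from paleodown.spline import make_downscale_plan

params = FixtureParams(seed=11, noise_sd=0.0)
paleo, control = make_climatology_pair(params, "precip")
baseline, _ = make_fine_baseline(params, "precip")

plan = make_downscale_plan(
    params.coarse_spec, np.ones(params.coarse_spec.shape, bool), params.fine_spec
)
products = {}
for method in ("raw", "roa"):
    delta = compute_delta(paleo, control, method)
    fine = [downscale_field(g, params.fine_spec, plan=plan) for g in delta.months]
    products[method] = apply_delta(baseline, DeltaField("precip", method, fine))

month = 5  # June
report = compare_methods(
    products["raw"].months[month],
    products["roa"].months[month],
    paleo.months[month],
)
print(report.to_text())
print()
print("Both products track the coarse paleo rainfall, but the additive")
print("calibration correlates more strongly; the ratio method modulates")
print("the baseline's departure from the control run and widens ranges.")
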