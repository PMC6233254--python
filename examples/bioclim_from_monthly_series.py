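"""All 19 bioclimatic variables for a single location's monthly climate.

Uses a mid-latitude seasonal cycle (warm wet summers) and prints each
variable with its encoding: temperatures in tenths of a degree Celsius,
precipitation totals in millimetres.
"""

import numpy as np

from paleodown import bioclim_values
from paleodown.bioclim import ALL_VARIABLES, TEMPERATURE_VARS, round_half_away

months = np.arange(12)
tmean = 12.0 + 10.0 * np.sin((months - 3) * np.pi / 6.0)
tmin = tmean - 6.0
tmax = tmean + 6.0
precip = 60.0 + 45.0 * np.sin((months - 4) * np.pi / 6.0)

vals = bioclim_values(
    tmean[:, None], precip[:, None], tmin[:, None], tmax[:, None]
)

labels = {
    "bio1": "annual mean temperature", "bio2": "mean diurnal range",
    "bio3": "isothermality", "bio4": "temperature seasonality (sd*100)",
    "bio5": "max temp of warmest month", "bio6": "min temp of coldest month",
    "bio7": "temperature annual range", "bio8": "mean temp, wettest quarter",
    "bio9": "mean temp, driest quarter", "bio10": "mean temp, warmest quarter",
    "bio11": "mean temp, coldest quarter", "bio12": "annual precipitation",
    "bio13": "precip of wettest month", "bio14": "precip of driest month",
    "bio15": "precip seasonality (CV)", "bio16": "precip of wettest quarter",
    "bio17": "precip of driest quarter", "bio18": "precip of warmest quarter",
    "bio19": "precip of coldest quarter",
}
for name in ALL_VARIABLES:
    v = float(vals[name][0])
    if name in TEMPERATURE_VARS:
        enc = int(round_half_away(np.array(v * 10.0)))
        print(f"{name:>6}  {labels[name]:34} {enc:6d}  (deg C * 10)")
    else:
        enc = int(round_half_away(np.array(v)))
        unit = "mm" if name not in ("bio3", "bio4", "bio15") else ""
        print(f"{name:>6}  {labels[name]:34} {enc:6d}  {unit}")

print()
print("Quarters are circular 3-month windows; the wettest quarter here")
print("is the late-summer window, so bio8 sits near the annual maximum.")
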