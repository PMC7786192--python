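"""Compute per-animal temperature-humidity index from weather records.

Builds a two-station weather table with a seasonal temperature cycle,
assigns animals to stations, and averages the 15-45 day pre-slaughter
window into one THI value per animal.
"""

import numpy as np
import pandas as pd

from reactnorm import animal_thi, compute_thi

rng = np.random.default_rng(1)

days = pd.date_range("2019-01-01", periods=365, freq="D")
doy = days.dayofyear.to_numpy()
weather = pd.concat([
    pd.DataFrame({
        "station_id": sid,
        "date": days,
        # warm south (shift +4 C), cool north; sinusoidal season + noise
        "t_max": base + 12 * np.sin(2 * np.pi * (doy - 100) / 365)
        + rng.normal(0, 2, len(days)),
        "rh_mean": np.clip(65 + rng.normal(0, 8, len(days)), 20, 100),
    })
    for sid, base in [("north", 16.0), ("south", 20.0)]
], ignore_index=True)

animals = pd.DataFrame({
    "animal_id": [f"hw{i:03d}" for i in range(8)],
    "farm_location": ["north", "south"] * 4,
    "slaughter_date": pd.to_datetime([
        "2019-04-15", "2019-06-20", "2019-08-05", "2019-09-30",
        "2019-07-12", "2019-10-25", "2019-11-18", "2019-12-05",
    ]),
})

table = animal_thi(weather, animals)  # default window: 45..15 days before
print("Single reading: THI at T=30 C, H=50% ->", compute_thi(30.0, 50.0))
print()
print(table.round(3).to_string(index=False))
print()
print("raw_thi is the heat-load index averaged over each animal's pre-")
print("slaughter window; c is its z-score across the cohort and is the")
print("environmental gradient the reaction-norm models regress on.")
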