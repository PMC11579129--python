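"""ndRMS as a function of inter-electrode distance on a simulated grid.

Simulates resting epicortical activity under a 96-contact high-density
grid (8x12, 3 mm pitch, 1 mm contacts), computes ndRMS for all 4560
electrode pairs, and averages per equidistant IED bin (bins with fewer
than 10 pairs are dropped).  Nearby electrodes share most of their
signal (low ndRMS); the statistic rises toward the white-noise floor
sqrt(2) with distance.
"""

import numpy as np

from ndrms import (
    bin_equidistant,
    make_square_layout,
    ndrms_per_pair,
    pair_distance_table,
)
from ndrms.simulate import default_config, generate_dataset
from ndrms.stats import ndrms_by_ied

layout = make_square_layout(8, 12, 3.0, 1.0)
config = default_config(seed=1, duration_s=6.0)
recording, _ = generate_dataset(config, layout)
print(f"simulated {recording.n_channels} channels, {recording.duration_s:.0f} s "
      f"at {recording.fs_hz:.0f} Hz")

pairs = pair_distance_table(layout)
bins = bin_equidistant(pairs, min_pairs=10)
values = ndrms_per_pair(recording, pairs, mode="stream")  # anesthesia-style stream
curve = ndrms_by_ied(values, bins, band="unfiltered")

print(f"\n{len(pairs)} pairs in {len(bins)} IED bins (>= 10 pairs each)")
print("IED (mm)  pairs  mean ndRMS")
for _, row in curve.iterrows():
    print(f"  {row.ied_mm:6.1f}  {row.n_pairs:5d}  {row.value:.3f}")

from scipy.stats import spearmanr

rho = spearmanr(curve["ied_mm"], curve["value"]).statistic
print(f"\nSpearman(IED, ndRMS) = {rho:.3f}  -> non-shared information grows with distance")
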