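"""Mapping task-responsive electrodes with high-frequency band power.

Simulates an awake recording with an 80 Hz source switched on during
active trial windows under one corner of a small grid, segments rest
(1.5 s before stimulus) and active (1.5 s after) trials, and correlates
trial-mean 64-128 Hz power with the binary task regressor.  Reported per
electrode: Pearson r, signed R^2 = sign(r) * r^2, t-distribution p, and
Bonferroni-corrected significance.
"""

import numpy as np

from ndrms import make_square_layout, segment_trials, signed_r2_map, trial_band_power
from ndrms.simulate import Broadband, SimConfig, TaskModulation, generate_dataset

layout = make_square_layout(2, 4, 3.0, 1.0)
config = SimConfig(
    duration_s=35.0,
    broadband=Broadband(amplitude=2.0),
    sensor_noise_sd=1.0,
    task=TaskModulation(freq_hz=80.0, amplitude=6.0, center_mm=(0.0, 0.0),
                        radius_mm=1.5),
    seed=8,
)
recording, events = generate_dataset(config, layout, n_trials=10, isi_s=3.0)
print(f"{len(events)} stimulus events; task patch under electrode E01 at (0, 0) mm")

trials = segment_trials(recording, events, scheme="fixed_1p5s")
powers = trial_band_power(trials, band=(64.0, 128.0))
result = signed_r2_map(powers, trials.label, alpha=0.05,
                       channel_id=layout.electrode_id)

print("\nchannel      r  signed_R2          p  significant")
for _, row in result.iterrows():
    print(f"{row.channel:7s} {row.r:6.3f}  {row.signed_r2:9.3f}  {row.p:9.2e}  "
          f"{bool(row.significant)}")
print("\nElectrodes near the simulated patch show positive signed R^2 "
      "(more 64-128 Hz power during speech than rest); significance is "
      f"Bonferroni-thresholded at 0.05/{result.attrs['n_channels_tested']}.")
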