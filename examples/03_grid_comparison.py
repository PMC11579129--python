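"""HD vs UHD grids at matched inter-electrode distances.

A 3 mm square lattice (HD) and a 0.9 mm triangular lattice (UHD) share
two comparable IEDs: 3.0 vs 3.1 mm and 4.2 vs 4.1 mm.  At those IEDs the
per-band ndRMS values (eight dyadic bands plus unfiltered, nine values
per grid) are compared with two-sided Wilcoxon rank-sum tests,
Bonferroni-corrected over the matched IEDs.  Smaller contacts average
over less tissue, so the UHD grid records more non-shared signal.
"""

import numpy as np
import pandas as pd

from ndrms import (
    bandpass_filter,
    bin_equidistant,
    compare_grids,
    default_bandset,
    make_hex_layout,
    make_square_layout,
    matched_ied_bins,
    ndrms_per_pair,
    pair_distance_table,
)
from ndrms.preprocess import band_name
from ndrms.simulate import fine_grained_config, generate_dataset
from ndrms.stats import ndrms_by_ied

config = fine_grained_config(seed=4, duration_s=2.0)


def band_table(layout):
    rec, _ = generate_dataset(config, layout)
    pairs = pair_distance_table(layout)
    bins = bin_equidistant(pairs, min_pairs=10)
    rows = []
    for band in default_bandset():
        filtered = bandpass_filter(rec, band)
        values = ndrms_per_pair(filtered, pairs, mode="stream")
        rows.append(ndrms_by_ied(values, bins, band_name(band)))
    return bins, pd.concat(rows, ignore_index=True)


hd_bins, hd = band_table(make_square_layout(4, 6, 3.0, 1.0))
uhd_bins, uhd = band_table(make_hex_layout(5, 8, 0.9, 0.2))

matched = matched_ied_bins(hd_bins, uhd_bins, tolerance_mm=0.2)
print("matched IEDs (HD vs UHD):", [(round(a, 1), round(b, 1)) for *_, a, b in matched])

result = compare_grids(hd, uhd, matched, alpha=0.05)
print("\nper matched IED: rank-sum W (lower sample), two-sided p, Bonferroni p")
print(result.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\n'significant' means the two grids' per-band ndRMS distributions "
      "differ at that IED after correction.")
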