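"""Preprocess a cohort: smoothing, baseline removal, SNV, and SNR estimation.

Each spectrum passes through Savitzky-Golay smoothing (window 15, order 1),
iterative degree-15 polynomial baseline removal, and Standard Normal
Variate normalisation, in that fixed order.
"""

import numpy as np

from sersdx import (
    CohortConfig,
    baseline_correct,
    estimate_snr,
    generate_cohort,
    preprocess_dataset,
    savgol_smooth,
)

ds = generate_cohort(CohortConfig(seed=0, n_target=4, n_control=4))

raw = ds.intensities[0]
smoothed = savgol_smooth(raw)
corrected, baseline = baseline_correct(smoothed)
print(f"raw range:        {raw.min():.3f} .. {raw.max():.3f} a.u.")
print(f"baseline range:   {baseline.min():.3f} .. {baseline.max():.3f} a.u.")
print(f"corrected range:  {corrected.min():.3f} .. {corrected.max():.3f} a.u.")
print(f"residual-based SNR of this spectrum: {estimate_snr(raw, smoothed):.1f}")

pp = preprocess_dataset(ds)
means = pp.intensities.mean(axis=1)
sds = pp.intensities.std(axis=1, ddof=1)
print(f"after SNV every row has mean ~0 (max |mean| = {np.abs(means).max():.2e}) "
      f"and sd 1 (max |sd-1| = {np.abs(sds - 1).max():.2e})")
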