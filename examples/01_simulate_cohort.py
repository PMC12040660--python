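"""Generate a synthetic serum SERS cohort and inspect its structure.

The generator emulates a two-group case-control study: 48 Target and 30
Control subjects, 3 replicate spectra each, sharp vibrational peaks on a
broad autofluorescent background, and a twofold Target/Control amplitude
ratio at the 632, 728 and 1062 cm^-1 effect bands.
"""

import numpy as np

from sersdx import CohortConfig, generate_cohort

cfg = CohortConfig(seed=0)
ds = generate_cohort(cfg)

subjects = ds.subjects()
print(f"spectra:  {ds.n_spectra} rows x {ds.n_channels} channels")
print(f"subjects: {(subjects['group'] == 'Target').sum()} Target, "
      f"{(subjects['group'] == 'Control').sum()} Control")
print(f"axis:     {ds.axis[0]:.0f}..{ds.axis[-1]:.0f} cm^-1, "
      f"step {ds.axis[1] - ds.axis[0]:.0f}")

# the planted effect is visible in the raw group means at 632 cm^-1
i = int(np.argmin(np.abs(ds.axis - 632.0)))
t_mean = ds.intensities[ds.group == "Target", i].mean()
c_mean = ds.intensities[ds.group == "Control", i].mean()
print(f"mean raw intensity at 632 cm^-1: Target {t_mean:.3f}, Control {c_mean:.3f}")
print("(the Target excess at this band is the signal the classifier must find)")
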