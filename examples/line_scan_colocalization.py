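"""Line scan across a single vesicle: per-channel intensity co-localization.

Renders one noise-free triple-positive vesicle and samples all four
channels along a horizontal segment through its center. Co-localization
shows up as coincident peaks; the profile of each channel follows the
Gaussian point-spread cross-section.
"""

import numpy as np

from evquant import CHANNELS, FieldSpec, MarkerCombination, line_scan, render_field
from evquant.synthetic_imaging import EVTruthRecord

spec = FieldSpec(width=64, height=64, n_evs=1, shot_noise=False, read_noise_sigma=0.0)
vesicle = EVTruthRecord(
    ev_id=0,
    center_x=32.0,
    center_y=32.0,
    combination=MarkerCombination(cd63=True, cd9=True, cd98=True),
    amplitudes=(2000.0, 2500.0, 1800.0, 2200.0),
)
field = render_field(spec, [vesicle])

profile = line_scan(field, p0=(32.0, 22.0), p1=(32.0, 42.0), width=1)

print("position  " + "  ".join(f"{c:>6s}" for c in CHANNELS))
for i in range(0, len(profile.positions), 2):
    row = "  ".join(f"{profile.profiles[c][i]:6.0f}" for c in CHANNELS)
    print(f"{profile.positions[i]:8.0f}  {row}")

peaks = {c: float(profile.positions[np.argmax(profile.profiles[c])]) for c in CHANNELS}
print("\npeak position along the scan, per channel:", peaks)
print("coincident peaks across channels indicate the markers sit on the same vesicle")
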