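"""Measure two-channel signal overlap with the thresholded Manders M1.

Generates three replicate two-channel fields for a strongly colocalised pair
(75% of the green signal inside red foci) and a weakly colocalised pair
(20%), then runs the full workflow on each field: rolling-ball background
subtraction, isodata auto-thresholding, intensity-weighted M1.
"""

import numpy as np

from coccoloc import ImagingSpec, coloc_pipeline, render_coloc_pair

for overlap in (0.75, 0.20):
    fields = []
    for s in range(3):
        pair = render_coloc_pair(overlap, ImagingSpec(seed=100 + s))
        fields.append((pair.green.astype(float), pair.red.astype(float)))
    table, summary = coloc_pipeline(fields, background_radius_px=50)
    per_field = ", ".join(f"{v:.3f}" for v in table["m1"])
    print(f"generator overlap {overlap:.2f}:  per-field M1 = [{per_field}]  "
          f"mean = {summary['mean_m1']:.3f} +/- {summary['sd_m1']:.3f}")

print()
print("M1 is the fraction of green intensity (within the green auto-threshold")
print("selection) that falls on pixels where the red channel exceeds its own")
print("auto-threshold: ~0.7-0.8 indicates colocalised foci, ~0.2 mostly")
print("non-overlapping ones.")
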