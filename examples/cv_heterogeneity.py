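"""Quantify membrane-fluorescence heterogeneity with the polar-transform CV.

Renders a cohort of punctate cells and a cohort of homogeneous-ring cells
(20 each, default imaging noise), measures each cell's CV factor and compares
the groups with a two-tailed unpaired t-test.
"""

import math

import numpy as np

from coccoloc import CellSpec, ImagingSpec, cell_cv, cv_group_compare, estimate_centre, render_cell

rng = np.random.default_rng(0)
cohorts = {}
for pattern in ("punctate", "homogeneous_ring"):
    results = []
    for _ in range(20):
        base = rng.uniform(0, 2 * math.pi)
        angles = tuple((base + 2 * math.pi * k / 6) % (2 * math.pi) for k in range(6)) \
            if pattern == "punctate" else None
        spec = CellSpec(centre=(23.5, 23.5), radius_px=8, pattern=pattern,
                        n_puncta=6 if angles else 0, puncta_angles=angles, cytoplasm_level=0.2)
        image = render_cell(spec, ImagingSpec(seed=int(rng.integers(2**31))), 48).image
        centre = estimate_centre(image, (23.5, 23.5), 8)  # refine the annotated centre
        results.append(cell_cv(image, centre, 8, remove_cytoplasm=True))
    cohorts[pattern] = results

comp = cv_group_compare(cohorts["punctate"], cohorts["homogeneous_ring"])
print(f"punctate cohort:     CV = {comp.mean_a:5.1f} +/- {comp.sd_a:.1f}  (n={comp.n_a})")
print(f"homogeneous cohort:  CV = {comp.mean_b:5.1f} +/- {comp.sd_b:.1f}  (n={comp.n_b})")
print(f"two-tailed unpaired t-test: t = {comp.t:.1f}, p = {comp.p:.2e}  {comp.stars}")
print()
print("A high CV factor (100*sigma/mu of the fluorescence-by-angle profile)")
print("marks a heterogeneous, punctate membrane distribution; low values a")
print("uniform ring. The stars follow the usual P<0.05/0.01/0.001/0.0001 scale.")
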