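# coccoloc

Quantitative image analysis of membrane-protein localisation in coccoid
bacteria. Many membrane proteins of *Staphylococcus aureus* — phospholipid
synthesis enzymes such as PlsY and CdsA, the flotillin FloT, the respiratory
protein CydB — are not spread uniformly over the ~1 µm cell membrane but
accumulate in discrete puncta and at the division septum, while others
(e.g. SecY) stay close to homogeneous. `coccoloc` implements the three
measurements used to establish and dissect that heterogeneity from widefield
fluorescence micrographs, together with a synthetic coccoid-cell generator
with known ground truth, so the whole pipeline is testable without any
experimental data.

## The three measurements

**Polar-transform CV factor.** A cell image is resampled to polar
coordinates about the cell centre and reduced to the mean fluorescence per
angle, I(θ). Heterogeneity is summarised as the scaled coefficient of
variation

    CV = 100 · σ / µ

with σ and µ the (population) standard deviation and mean of I(θ) and 100 an
arbitrary scaling factor. Punctate cells score high (≈15–25 at typical
contrasts), homogeneous rings low (≈2–5). Because σ and µ scale together,
the statistic is invariant to intensity and nearly invariant to cell size.
For convolved images the cytoplasmic signal is first removed by excluding
the central disc holding 20% of the cell area (r_min = r_max·√0.2). Groups
of cells (default n = 20 per group) are compared with a two-tailed unpaired
Student's t-test.

**Donor-photobleaching FRET.** Energy transfer to an acceptor slows the
donor fluorophore's photobleaching. Each ROI's intensity trace over a 6-min
continuous acquisition (720 frames at 0.5 s/frame) is fitted with
I(t) = A·e^(−t/τ) + B, and the interaction efficiency is

    E = 1 − τ_PB / τ′_PB

where τ_PB is the donor-only time constant and τ′_PB the time constant in
the presence of the candidate acceptor. E is reported in percent, with a
bootstrap confidence interval over cells, at whole-cell or subcellular
(septum/periphery × dividing/non-dividing) resolution; slightly negative
values are reported unclipped.

**Thresholded Manders colocalisation.** Per two-channel field: rolling-ball
background subtraction (grayscale opening with a ball element, default
radius 50 px), isodata auto-threshold of the green channel to define the
analysis selection, the red channel's own isodata threshold to define
colocalised pixels, then the intensity-weighted M1 — the fraction of green
signal residing on red-positive pixels — summarised over replicate fields
(default 3).

## Worked example

`examples/cv_heterogeneity.py` builds two synthetic cohorts of 20 cells
(6 puncta at 3× contrast vs a homogeneous ring, default camera noise),
refines each annotated centre, measures each cell's CV and compares groups:

```
punctate cohort:     CV =  16.1 +/- 0.5  (n=20)
homogeneous cohort:  CV =   2.9 +/- 0.2  (n=20)
two-tailed unpaired t-test: t = 118.7, p = 1.86e-50  ****
```

The punctate cohort's fluorescence-by-angle profile varies ~16% around its
mean; the homogeneous cohort's residual 2.9 reflects photon and camera noise
alone, and the t-test separates the groups decisively. The other scripts in
`examples/` do the same for FRET (recovering E = 19.9% for a true-20% pair
with τ_PB ≈ 100 vs τ′_PB ≈ 125 frames) and Manders M1 (mean 0.740 vs 0.181
for generator overlaps of 0.75 and 0.20).

The full pipeline is also scriptable from the shell:

```
coccoloc reproduce --seed 0 --out run/
```

generates a complete dataset (cell crops + annotations, bleaching traces,
colocalisation fields), runs all three analyses, and writes result tables,
figures and a pass/fail report of the qualitative findings the synthetic
suite emulates (punctate vs homogeneous discrimination, dose-dependent CV
collapse, FRET recovery, M1 ordering). Every run writes its fully resolved
YAML config next to its outputs and is byte-reproducible from seed + config.

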