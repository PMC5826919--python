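# Methods

This note documents the models behind `coccoloc`, the parameters that
matter, the synthetic study the default configuration encodes, and the
numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and unit conventions

One convention throughout: x = column, y = row, origin at the centre of the
top-left pixel, 0-based; angles in radians, counter-clockwise from the +x
axis. Default geometry assumes 65 nm/px, so a 1 µm coccoid cell has radius
≈ 8 px; bleaching acquisitions default to 720 frames, i.e. 6 min of
continuous imaging at 0.5 s/frame (500 ms exposure, negligible readout
overhead assumed — the true overhead of such acquisitions is instrument-
specific and unknown). Both are configurable.

## Synthetic coccoid cells

A 2-D mid-plane model, not a 3-D shell projection: the membrane is an
annulus with Gaussian radial cross-section (sd `ring_sigma_px`, default
1.5 px) centred at the cell radius. The CV analysis consumes mid-plane
images, so the extra realism of a projected shell would only change the
radial intensity profile it averages over.

- **Puncta** are angular Gaussian bumps multiplying the ring intensity
  (angular sd 0.15 rad by default; `puncta_contrast` is the peak-to-baseline
  ratio). This keeps a closed-form ground-truth angular profile — the
  modulation m(θ) is known exactly, so tests can count maxima and predict
  CV values analytically.
- **Septa** are straight chord bands through the centre (Gaussian
  cross-section, default sd 1.5 px) clipped to the cell disc.
- **Cytoplasm** is a uniform interior disc at `cytoplasm_level` (default
  0.2) of the ring peak, emulating out-of-focus and cytoplasmic background
  in convolved (non-deconvolved) images.
- **Dose-dependence** is emulated by `uniform_mix`: the angular modulation is
  linearly mixed toward a uniform ring, standing in for over-expression
  flattening a punctate pattern.

The imaging chain is the standard widefield camera model: Gaussian PSF
(default sd 1.6 px ≈ 105 nm, a reasonable width for a high-NA objective at
GFP wavelengths and 65 nm sampling), Poisson shot noise with
`photon_scale` photons per intensity unit (default 0.2, i.e. ≈ 200 photons
at the 1000-count ring peak, ~7% shot noise), additive Gaussian read noise
(default 10 counts), quantisation and clipping to 8/12/16-bit (default 12,
matching the dynamic range used for time-lapse acquisition). Identical
seeds give bit-identical images; `photon_scale = inf` and zero read noise
give a noise-free chain for exactness tests.

What the generator does **not** emulate: 3-D structure and Z-stacks,
spatially correlated background (other than the optional smooth gradients
used in tests), cell-to-cell size and brightness variability beyond what a
configuration sweeps in, focus drift, and deconvolution artefacts. Passing
tests therefore demonstrate correctness of the estimators under a realistic
noise model — not robustness to every failure mode of real micrographs.

## CV factor

The heterogeneity statistic is

CV = 100 · σ/µ,

σ and µ being the population standard deviation and mean of the mean-
intensity-per-angle profile. The literature this implements prints the
formula ambiguously (σ/(100µ) in one place, µ/σ in another) while its
reported values (≈13–25) are only consistent with 100·σ/µ; the constant is
explicitly arbitrary and is a parameter (`scale`). Population rather than
sample sd: with 360 angular bins the difference is < 0.2%; also
configurable (`ddof`).

The polar transform samples the image bilinearly at
θ_i = 2πi/n_angle_bins (default 360) and n_radial_samples radii up to
max_radius (default max_radius+1 samples). The profile averages radii
uniformly, matching the behaviour class of the standard polar-transformer
plug-in. Cytoplasm removal excludes the central disc holding 20% of the
cell area (r_min = r_max·√0.2 ≈ 0.447·r_max) and is intended for convolved
images; deconvolved images have little cytoplasmic signal and are analysed
without it. Cells whose profile mean falls below a configurable floor
(default 1e-9) are rejected rather than returning unstable ratios.

A second estimator, `binned_angular_profile`, reproduces the estimand of
per-pixel angle binning (bin-width angular averaging, area-weighted radii)
through the polar transform. It exists to cross-validate the transform
against a brute-force per-pixel oracle on equal terms. At 65 nm sampling
(radius ~8–12 px) the pixel-binning oracle itself fluctuates several
percent per bin — few pixels per bin crossed with the steep radial profile
— so the oracle-equivalence check is run on finely sampled cells (radius
20–28 px), where the comparison is well-conditioned; the pooled relative
RMS there is below 2%.

Cell centres may be taken from annotations or refined as the intensity-
weighted centroid of isodata-thresholded pixels in a 1.5·radius window
(both paths exist because how centres were chosen upstream is generally
unknown). Note the centroid is pulled toward bright foci on strongly
punctate cells; the CV statistic is insensitive to sub-pixel centre error,
but the 0.5 px refinement contract is stated for ring-like cells.

Group comparison: classic pooled-variance two-tailed unpaired Student's
t-test, n = 20 cells per group by default, stars at P < 0.05/0.01/0.001/
0.0001.

## Donor-photobleaching FRET

Model: I(t) = A·e^(−t/τ) + B, fitted by bounded least squares
(`scipy.optimize.curve_fit`, xtol = ftol = 1e-14), initialised from the
tail median (B) and a log-linear regression of the baseline-subtracted
early frames (A, τ). The offset term absorbs the non-bleaching background
of fixed cells on slides and can be disabled (`with_offset=False`); a pure
rate-only linear reading of "decay rate" was rejected because the
efficiency formula is stated in time constants. Trailing frames stuck at
the quantisation floor are trimmed before fitting (threshold configurable).
Fits are honest: constant, rising or degenerate traces return
`converged=False` with a diagnostic rather than a number.

Efficiency: E = 1 − τ_PB/τ′_PB with τ per arm the arithmetic mean of
converged per-cell estimates (one construct, one τ); the per-cell-E mean is
also reported on the result object for comparison. Negative E is reported
unclipped — it means the donor happened to bleach faster in the acceptor
strain, not a physical negative transfer. Uncertainty is a seeded bootstrap
over cells within arms (default 1,000 resamples); no analytic error
propagation is attempted because the per-cell τ distribution is the natural
unit of replication. Subcellular analysis groups traces by
(division state × ROI), requires each compartment's own donor-only arm, and
flags missing compartments absent rather than zero.

## Manders colocalisation

Rolling-ball background: grayscale opening with a true ball (spherical-cap
height) structuring element, radius 50 px by default, implemented with
scipy's non-flat grey erosion/dilation. The classic paraboloid-shrink
approximation differs negligibly at radii much larger than the features but
would not match a direct sliding-window oracle exactly, which the tests
require. Thresholds use the isodata (iterative intermeans) rule; the
analysis selection is defined on the green (reference/FITC) channel and the
red channel's own threshold defines colocalised pixels within it — both
channel-role assignments are available. M1 is intensity-weighted (sums of
green intensity), not pixel-count based. Replicate fields (default 3) are
summarised as mean ± sd; a single field's sd is flagged undefined.

The two-channel generator builds foci as hard discs (green radius 2.2 px
nested inside red 3.2 px) on rings of radius 10 px, four foci per cell,
with the requested fraction of green foci coincident with red foci and the
rest placed half-way between red positions. On the ideal images M1 then
equals the requested overlap up to whole-focus and per-disc pixel
quantisation (~±0.02); disc sizes and spacing were chosen so that distinct
foci remain disjoint after PSF blur.

## Pipeline and reproducibility

All randomness flows from one top-level seed; each stage derives a
substream seed from it, so stages are independently reproducible. Every
command writes its fully resolved YAML configuration next to its outputs
and a run is reproducible from that file alone; result tables are
byte-identical across reruns. The one-command reproduction
(`coccoloc reproduce`) generates the default study — two CV cohorts of 20
cells, two FRET arms of 20 traces (true E = 0.20), three field pairs at
overlaps 0.75 and 0.20 — analyses it, and reports each qualitative check
pass/fail; with deliberately extreme noise it reports failures rather than
crashing.

Problem sizes used by the test suite and acceptance script — 20 cells per
cohort, 200 fit replicates per τ, 3 fields per condition, 128 px coloc
fields — are the study's own defaults and keep a full run in the low
minutes on one core.

## Known limitations

- The CV statistic is count-free by design: it cannot distinguish 4 bright
  puncta from 8 dimmer ones at equal angular variance.
- A fixed-width PSF genuinely breaks exact size-invariance of CV across
  cell radii (angular features blur more on smaller cells); the invariance
  tests therefore use unblurred patterns, and cross-radius comparisons on
  real data should hold magnification constant.
- Mono-exponential decay is an approximation; multi-population bleaching
  shows up as structured residuals (`residual_rms`), not as a second fitted
  component.
- Isodata is one member of the intermeans threshold family; other variants
  can be plugged in where a different upstream workflow must be matched.
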