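"""Synthetic coccoid-cell fluorescence microscopy with known ground truth.

Generates diffraction-limited widefield images of ~1 µm coccoid cells whose
membrane fluorescence is homogeneous, punctate (discrete foci) or septally
concentrated, plus mono-exponential photobleaching traces and two-channel
colocalisation fields with a controllable overlap fraction.  Every generator
is deterministic under its seed and returns the noise-free ideal image and
geometry masks alongside the noisy render, so downstream estimators can be
tested against exact ground truth.

The imaging model is a standard widefield camera chain: the pattern intensity
is convolved with a Gaussian PSF, shot noise is Poisson in photons
(``photon_scale`` photons per intensity unit), camera read noise is additive
Gaussian, and the result is quantised to the sensor bit depth.

Default scales assume 65 nm/px, so a 1 µm cell has radius ~8 px; bleaching
acquisitions default to 720 frames (6 min at 0.5 s/frame).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError

PATTERNS = ("homogeneous_ring", "punctate", "septal", "ring_plus_septum")

#: default membrane-ring radial cross-section (Gaussian sd, px)
DEFAULT_RING_SIGMA_PX = 1.5
#: default angular sd of a punctum (rad)
DEFAULT_PUNCTA_SIGMA_RAD = 0.15
#: pixel size the default geometry assumes (nm); 1 µm cell -> radius ~8 px
DEFAULT_PIXEL_SIZE_NM = 65.0
#: bleaching frame interval (s); 6 min of continuous acquisition -> 720 frames
DEFAULT_FRAME_INTERVAL_S = 0.5
DEFAULT_BLEACH_FRAMES = 720


@dataclass(frozen=True)
class CellSpec:
    """Geometry and labelling pattern of one synthetic coccoid cell.

    The membrane is an annulus with Gaussian radial cross-section of sd
    ``ring_sigma_px`` centred at ``radius_px``.  Puncta are angular Gaussian
    bumps multiplying the ring intensity; ``puncta_contrast`` is the ratio of
    punctum peak to ring baseline.  The septum is a straight chord band
    through the centre at orientation ``septum_angle``.  ``cytoplasm_level``
    adds a uniform interior disc as a fraction of the ring peak intensity.
    """

    centre: tuple[float, float]
    radius_px: float
    pattern: str = "homogeneous_ring"
    n_puncta: int = 0
    puncta_contrast: float = 3.0
    puncta_angles: tuple[float, ...] | None = None
    cytoplasm_level: float = 0.0
    septum_angle: float = 0.0
    ring_amplitude: float = 1000.0
    ring_sigma_px: float = DEFAULT_RING_SIGMA_PX
    puncta_sigma_rad: float = DEFAULT_PUNCTA_SIGMA_RAD
    septum_sigma_px: float = DEFAULT_RING_SIGMA_PX
    #: mixing weight toward a uniform ring: 0 = full pattern, 1 = homogeneous
    uniform_mix: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ParameterError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if self.radius_px < 3:
            raise ParameterError("radius_px must be >= 3 px (ring unresolvable below)")
        if self.pattern == "punctate" and self.n_puncta < 1:
            raise ParameterError("punctate pattern requires n_puncta >= 1")
        if self.n_puncta < 0:
            raise ParameterError("n_puncta must be >= 0")
        if self.puncta_contrast < 1:
            raise ParameterError("puncta_contrast must be >= 1")
        if self.cytoplasm_level < 0:
            raise ParameterError("cytoplasm_level must be >= 0")
        if not 0.0 <= self.uniform_mix <= 1.0:
            raise ParameterError("uniform_mix must be in [0, 1]")
        if self.puncta_angles is not None:
            angles = tuple(float(a) for a in self.puncta_angles)
            if len(angles) != self.n_puncta:
                raise ParameterError("puncta_angles length must equal n_puncta")
            if any(not (0.0 <= a < 2 * math.pi) for a in angles):
                raise ParameterError("puncta_angles must lie in [0, 2*pi)")
            object.__setattr__(self, "puncta_angles", angles)

    def resolved_puncta_angles(self) -> tuple[float, ...]:
        """Punctum angles, evenly spaced when not given explicitly."""
        if self.puncta_angles is not None:
            return self.puncta_angles
        return tuple(2 * math.pi * k / self.n_puncta for k in range(self.n_puncta))


@dataclass(frozen=True)
class ImagingSpec:
    """Widefield camera model: Gaussian PSF, Poisson photons, Gaussian read noise.

    ``photon_scale`` is the expected number of photons at unit ideal intensity;
    ``math.inf`` disables shot noise.  Output is quantised and clipped to the
    sensor bit depth.  Identical seed and specs yield bit-identical images.
    """

    psf_sigma_px: float = 1.6
    photon_scale: float = 0.2
    read_noise_sd: float = 10.0
    bit_depth: int = 12
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px < 0:
            raise ParameterError("psf_sigma_px must be >= 0")
        if not self.photon_scale > 0:
            raise ParameterError("photon_scale must be > 0 (use math.inf for noise-free)")
        if self.read_noise_sd < 0:
            raise ParameterError("read_noise_sd must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ParameterError("bit_depth must be one of 8, 12, 16")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


@dataclass(frozen=True)
class BleachSpec:
    """Mono-exponential photobleaching acquisition.

    trace[t] = amplitude * exp(-t / tau_frames) + offset + N(0, noise_sd).
    """

    tau_frames: float
    amplitude: float = 1000.0
    offset: float = 0.0
    n_frames: int = DEFAULT_BLEACH_FRAMES
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_frames > 0:
            raise ParameterError("tau_frames must be > 0")
        if not self.amplitude > 0:
            raise ParameterError("amplitude must be > 0")
        if self.offset < 0:
            raise ParameterError("offset must be >= 0")
        if self.n_frames < 10:
            raise ParameterError("n_frames must be >= 10")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class CellRender:
    """One rendered cell: noisy image, ideal (pre-noise) image, geometry masks."""

    image: np.ndarray
    ideal: np.ndarray
    blurred: np.ndarray
    masks: dict[str, np.ndarray]
    puncta_masks: list[np.ndarray] = field(default_factory=list)
    spec: CellSpec | None = None


@dataclass
class FieldRender:
    """A multi-cell field with per-cell ground-truth annotations."""

    image: np.ndarray
    ideal: np.ndarray
    records: list  # list[CellRecord]; untyped to avoid circular import
    specs: list[CellSpec] = field(default_factory=list)


@dataclass
class ColocPair:
    """Two-channel field with a known intensity-overlap ground truth."""

    green: np.ndarray
    red: np.ndarray
    ideal_green: np.ndarray
    ideal_red: np.ndarray
    true_m1: float
    overlap_fraction: float


def _wrapped_angle_distance(theta: np.ndarray, angle: float) -> np.ndarray:
    d = np.abs(theta - angle) % (2 * math.pi)
    return np.minimum(d, 2 * math.pi - d)


def angular_modulation(spec: CellSpec, theta: np.ndarray) -> np.ndarray:
    """Closed-form angular intensity modulation m(theta) of the ring.

    For a punctate cell, m = 1 + (contrast - 1) * sum of angular Gaussian
    bumps; for homogeneous and septal-only patterns m = 1.  ``uniform_mix``
    linearly collapses the modulation toward 1 (dose-dependence emulation).
    """
    theta = np.asarray(theta, dtype=float)
    m = np.ones_like(theta)
    if spec.pattern in ("punctate",) and spec.n_puncta > 0:
        for a in spec.resolved_puncta_angles():
            d = _wrapped_angle_distance(theta, a)
            m += (spec.puncta_contrast - 1.0) * np.exp(-0.5 * (d / spec.puncta_sigma_rad) ** 2)
    return (1.0 - spec.uniform_mix) * m + spec.uniform_mix


def ideal_cell_image(
    spec: CellSpec, image_size: int | tuple[int, int]
) -> tuple[np.ndarray, dict[str, np.ndarray], list[np.ndarray]]:
    """Noise-free, unblurred intensity image of one cell plus geometry masks.

    Masks are computed on the unblurred geometry: ``membrane`` is the annulus
    within 2 ring sigmas of the nominal radius, ``cytoplasm`` the interior
    disc inside it, ``septum`` the chord band (when the pattern has one), and
    one boolean mask per punctum.
    """
    shape = (image_size, image_size) if np.isscalar(image_size) else tuple(image_size)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    cx, cy = spec.centre
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx) % (2 * math.pi)

    ring_radial = np.exp(-0.5 * ((r - spec.radius_px) / spec.ring_sigma_px) ** 2)
    ideal = np.zeros(shape, dtype=float)

    if spec.pattern in ("homogeneous_ring", "punctate", "ring_plus_septum"):
        ideal += spec.ring_amplitude * ring_radial * angular_modulation(spec, theta)

    if spec.pattern in ("septal", "ring_plus_septum"):
        # perpendicular distance from the chord through the centre
        d_perp = np.abs(-math.sin(spec.septum_angle) * dx + math.cos(spec.septum_angle) * dy)
        band = np.exp(-0.5 * (d_perp / spec.septum_sigma_px) ** 2)
        interior = np.where(r <= spec.radius_px, 1.0, np.exp(-0.5 * ((r - spec.radius_px) / spec.ring_sigma_px) ** 2))
        ideal += spec.ring_amplitude * band * interior

    inner = r < spec.radius_px - 2 * spec.ring_sigma_px
    if spec.cytoplasm_level > 0:
        ideal += spec.ring_amplitude * spec.cytoplasm_level * (r <= spec.radius_px)

    masks: dict[str, np.ndarray] = {
        "membrane": np.abs(r - spec.radius_px) <= 2 * spec.ring_sigma_px,
        "cytoplasm": inner,
    }
    if spec.pattern in ("septal", "ring_plus_septum"):
        d_perp = np.abs(-math.sin(spec.septum_angle) * dx + math.cos(spec.septum_angle) * dy)
        masks["septum"] = (d_perp <= 2 * spec.septum_sigma_px) & (r <= spec.radius_px + 2 * spec.ring_sigma_px)

    puncta_masks = []
    if spec.pattern == "punctate":
        for a in spec.resolved_puncta_angles():
            d = _wrapped_angle_distance(theta, a)
            puncta_masks.append(masks["membrane"] & (d <= 2 * spec.puncta_sigma_rad))
    return ideal, masks, puncta_masks


def apply_imaging(ideal: np.ndarray, imaging: ImagingSpec, *, rng: np.random.Generator | None = None) -> np.ndarray:
    """Blur-free noise + quantisation step of the camera model.

    Poisson shot noise at ``photon_scale`` photons per intensity unit,
    additive Gaussian read noise, rounding to integer grey levels, clipping
    to the bit depth.  A fresh generator is seeded from ``imaging.seed``
    unless ``rng`` is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(imaging.seed)
    signal = np.asarray(ideal, dtype=float) + imaging.background
    if math.isfinite(imaging.photon_scale):
        signal = rng.poisson(np.clip(signal, 0, None) * imaging.photon_scale) / imaging.photon_scale
    if imaging.read_noise_sd > 0:
        signal = signal + rng.normal(0.0, imaging.read_noise_sd, size=signal.shape)
    out = np.clip(np.rint(signal), 0, imaging.full_scale)
    return out.astype(imaging.dtype)


def _check_containment(spec: CellSpec, imaging: ImagingSpec, shape: tuple[int, int]) -> None:
    margin = spec.radius_px + 3 * spec.ring_sigma_px + 3 * imaging.psf_sigma_px
    cx, cy = spec.centre
    if cx - margin < 0 or cy - margin < 0 or cx + margin > shape[1] - 1 or cy + margin > shape[0] - 1:
        raise GeometryError(
            f"cell at centre {spec.centre} radius {spec.radius_px} px does not fit a "
            f"{shape[0]}x{shape[1]} frame with margin {margin:.1f} px"
        )


def render_cell(spec: CellSpec, imaging: ImagingSpec, image_size: int | tuple[int, int]) -> CellRender:
    """Render one cell through the full imaging chain.

    Returns the quantised noisy image, the ideal pattern, its PSF-blurred
    version, and ground-truth masks computed on the unblurred geometry.
    """
    shape = (image_size, image_size) if np.isscalar(image_size) else tuple(image_size)
    _check_containment(spec, imaging, shape)
    ideal, masks, puncta_masks = ideal_cell_image(spec, shape)
    blurred = ndimage.gaussian_filter(ideal, imaging.psf_sigma_px) if imaging.psf_sigma_px > 0 else ideal
    image = apply_imaging(blurred, imaging)
    return CellRender(image=image, ideal=ideal, blurred=blurred, masks=masks, puncta_masks=puncta_masks, spec=spec)


def render_field(cells: Sequence[CellSpec], imaging: ImagingSpec, field_size: int | tuple[int, int]) -> FieldRender:
    """Render several non-overlapping cells into one field.

    Cells must be pairwise non-overlapping (centre distance > sum of radii);
    annotations carry the ground-truth centres and radii.
    """
    from .io import CellRecord  # local import: io depends on nothing here

    shape = (field_size, field_size) if np.isscalar(field_size) else tuple(field_size)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            dist = math.hypot(a.centre[0] - b.centre[0], a.centre[1] - b.centre[1])
            if dist <= a.radius_px + b.radius_px:
                raise GeometryError(f"cells {i} and {j} overlap (centre distance {dist:.1f} px)")
    ideal = np.zeros(shape, dtype=float)
    records = []
    for i, spec in enumerate(cells):
        _check_containment(spec, imaging, shape)
        cell_ideal, _, _ = ideal_cell_image(spec, shape)
        ideal += cell_ideal
        records.append(
            CellRecord(
                cell_id=f"cell_{i:03d}",
                image_ref=None,
                centre=spec.centre,
                radius_px=spec.radius_px,
                group="",
                division_state="unknown",
            )
        )
    blurred = ndimage.gaussian_filter(ideal, imaging.psf_sigma_px) if imaging.psf_sigma_px > 0 else ideal
    image = apply_imaging(blurred, imaging)
    return FieldRender(image=image, ideal=ideal, records=records, specs=list(cells))


def simulate_bleach_trace(spec: BleachSpec):
    """Simulate one ROI photobleaching trace (mono-exponential plus offset).

    The returned :class:`~coccoloc.fret.BleachTrace` keeps the ground-truth
    time constant in ``true_tau`` for recovery tests.
    """
    from .fret import BleachTrace

    t = np.arange(spec.n_frames, dtype=float)
    ideal = spec.amplitude * np.exp(-t / spec.tau_frames) + spec.offset
    rng = np.random.default_rng(spec.seed)
    noisy = ideal + (rng.normal(0.0, spec.noise_sd, size=t.shape) if spec.noise_sd > 0 else 0.0)
    return BleachTrace(
        intensity=np.clip(noisy, 0.0, None),
        frame_index=np.arange(spec.n_frames),
        true_tau=spec.tau_frames,
    )


def simulate_bleach_stack(spec: BleachSpec, frame_shape: tuple[int, int], *, pixel_noise_sd: float | None = None) -> np.ndarray:
    """A uniform bleaching image stack (frame, y, x) with i.i.d. pixel noise.

    Per-pixel noise defaults to ``spec.noise_sd``; the ROI mean over n pixels
    then has sd noise_sd/sqrt(n), which extraction tests rely on.
    """
    t = np.arange(spec.n_frames, dtype=float)
    ideal = spec.amplitude * np.exp(-t / spec.tau_frames) + spec.offset
    stack = np.broadcast_to(ideal[:, None, None], (spec.n_frames, *frame_shape)).copy()
    sd = spec.noise_sd if pixel_noise_sd is None else pixel_noise_sd
    if sd > 0:
        rng = np.random.default_rng(spec.seed)
        stack = stack + rng.normal(0.0, sd, size=stack.shape)
    return np.clip(stack, 0.0, None)


def _spot_image(shape: tuple[int, int], positions: list[tuple[float, float]], radius: float, amplitude: float) -> np.ndarray:
    """Sum of hard discs; two-level by construction so thresholding is exact."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    img = np.zeros(shape, dtype=float)
    for (px, py) in positions:
        img = np.maximum(img, amplitude * ((xx - px) ** 2 + (yy - py) ** 2 <= radius**2))
    return img


def render_coloc_pair(
    overlap_fraction: float,
    imaging: ImagingSpec | None = None,
    *,
    field_size: int = 128,
    n_cells: int = 4,
    n_spots_per_cell: int = 4,
    cell_radius_px: float = 10.0,
    green_spot_radius: float = 2.2,
    red_spot_radius: float = 3.2,
    amplitude: float = 1000.0,
    seed: int | None = None,
) -> ColocPair:
    """Two-channel field whose ideal Manders M1 equals ``overlap_fraction``.

    Each cell carries ``n_spots_per_cell`` equal-intensity green foci on its
    periphery.  A fraction of them (rounded to whole foci) coincide with red
    foci; the rest sit half-way between red positions, clear of the red
    above-threshold region.  On the ideal (disc) images M1 is n_shared/n_spots
    up to per-disc pixel quantisation (discs are a handful of pixels), so the
    ground truth tracks ``overlap_fraction`` to ~0.02.  The noisy render goes
    through the usual PSF/noise chain.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ParameterError("overlap_fraction must lie in [0, 1]")
    if imaging is None:
        imaging = ImagingSpec()
    if seed is not None:
        imaging = replace(imaging, seed=seed)
    rng = np.random.default_rng(imaging.seed)

    shape = (field_size, field_size)
    n_total = n_cells * n_spots_per_cell
    n_shared_total = int(round(overlap_fraction * n_total))

    # cells on a jittered grid, kept inside the frame
    side = math.ceil(math.sqrt(n_cells))
    pitch = field_size / (side + 0.5)
    margin = cell_radius_px + red_spot_radius + 3 * imaging.psf_sigma_px + 2
    centres = []
    for i in range(n_cells):
        gx, gy = i % side, i // side
        cx = (gx + 0.75) * pitch + rng.uniform(-1.5, 1.5)
        cy = (gy + 0.75) * pitch + rng.uniform(-1.5, 1.5)
        centres.append((float(np.clip(cx, margin, field_size - 1 - margin)),
                        float(np.clip(cy, margin, field_size - 1 - margin))))

    green_pos: list[tuple[float, float]] = []
    shared_pos: list[tuple[float, float]] = []
    red_only_pos: list[tuple[float, float]] = []
    n_assigned = 0
    spacing = 2 * math.pi / n_spots_per_cell
    for ci, (cx, cy) in enumerate(centres):
        base = rng.uniform(0, 2 * math.pi)
        k = min(n_spots_per_cell, n_shared_total - n_assigned)
        n_assigned += k
        for s in range(n_spots_per_cell):
            a = base + s * spacing
            pos = (cx + cell_radius_px * math.cos(a), cy + cell_radius_px * math.sin(a))
            green_pos.append(pos)
            if s < k:
                shared_pos.append(pos)
            else:
                # red focus offset by half the spacing: disjoint from green discs
                a2 = a + spacing / 2
                red_only_pos.append((cx + cell_radius_px * math.cos(a2), cy + cell_radius_px * math.sin(a2)))

    ideal_green = _spot_image(shape, green_pos, green_spot_radius, amplitude)
    ideal_red = _spot_image(shape, shared_pos + red_only_pos, red_spot_radius, amplitude)

    # ground-truth M1 on the ideal pair: green intensity inside red discs
    red_region = ideal_red > 0
    true_m1 = float(ideal_green[red_region].sum() / ideal_green.sum()) if ideal_green.sum() > 0 else 0.0

    def _chain(ideal: np.ndarray, sub_rng: np.random.Generator) -> np.ndarray:
        blurred = ndimage.gaussian_filter(ideal, imaging.psf_sigma_px) if imaging.psf_sigma_px > 0 else ideal
        return apply_imaging(blurred, imaging, rng=sub_rng)

    green = _chain(ideal_green, rng)
    red = _chain(ideal_red, rng)
    return ColocPair(green=green, red=red, ideal_green=ideal_green, ideal_red=ideal_red,
                     true_m1=true_m1, overlap_fraction=overlap_fraction)
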