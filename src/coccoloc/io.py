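"""Image and annotation I/O plus cell-centre refinement.

Coordinate convention used throughout the package: x = column, y = row,
origin at the centre of the top-left pixel, 0-based; angles are measured
counter-clockwise from the +x axis in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_isodata

from .errors import CentringError, FormatError, ValidationError

DIVISION_STATES = ("non_dividing", "dividing", "unknown")

ANNOTATION_COLUMNS = ["cell_id", "centre_x", "centre_y", "radius_px", "group", "division_state"]
#: optional extra column linking each row to its image file
IMAGE_REF_COLUMN = "image_ref"


@dataclass
class CellRecord:
    """One annotated cell: where it is, which group it belongs to.

    ``roi_masks`` optionally carries named boolean masks (e.g. septum,
    periphery) of the same shape as the referenced image.
    """

    cell_id: str
    image_ref: str | Path | np.ndarray | None
    centre: tuple[float, float]
    radius_px: float
    group: str = ""
    division_state: str = "unknown"
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValidationError(f"cell {self.cell_id}: radius_px must be > 0")
        if self.division_state not in DIVISION_STATES:
            raise ValidationError(
                f"cell {self.cell_id}: division_state {self.division_state!r} not in {DIVISION_STATES}"
            )

    def validate_against(self, image: np.ndarray) -> None:
        """Check the record is consistent with its image (bounds, mask shapes)."""
        h, w = image.shape[-2:]
        x, y = self.centre
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValidationError(f"cell {self.cell_id}: centre {self.centre} outside {h}x{w} image")
        for name, mask in self.roi_masks.items():
            if mask.shape != (h, w):
                raise ValidationError(f"cell {self.cell_id}: roi mask {name!r} shape {mask.shape} != image {(h, w)}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a 2-D image or 3-D (frame, y, x) stack.

    Integer grey values are preserved losslessly.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted types for bad files
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: expected 2-D image or 3-D stack, got shape {arr.shape}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> Path:
    """Write a 2-D image or 3-D stack as (multi-page) TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image))
    return path


def write_annotations(path: str | Path, records: list[CellRecord]) -> Path:
    """Write cell annotations as a delimited table (one row per cell)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "cell_id": r.cell_id,
            "centre_x": r.centre[0],
            "centre_y": r.centre[1],
            "radius_px": r.radius_px,
            "group": r.group,
            "division_state": r.division_state,
            "image_ref": "" if r.image_ref is None or isinstance(r.image_ref, np.ndarray) else str(r.image_ref),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + [IMAGE_REF_COLUMN]).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path, image: np.ndarray | None = None) -> list[CellRecord]:
    """Read a cell annotation table; validate each row, reporting row numbers.

    An empty table yields an empty list.  When ``image`` is given, centres
    are checked against its bounds.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    records: list[CellRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        try:
            ref = row.get(IMAGE_REF_COLUMN, "")
            rec = CellRecord(
                cell_id=str(row["cell_id"]),
                image_ref=None if pd.isna(ref) or str(ref) == "" else str(ref),
                centre=(float(row["centre_x"]), float(row["centre_y"])),
                radius_px=float(row["radius_px"]),
                group="" if pd.isna(row["group"]) else str(row["group"]),
                division_state=str(row["division_state"]),
            )
            if image is not None:
                rec.validate_against(image)
            records.append(rec)
        except ValidationError as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return records


def estimate_centre(
    image: np.ndarray,
    approximate_centre: tuple[float, float],
    radius_px: float,
) -> tuple[float, float]:
    """Refine a cell centre as the intensity-weighted centroid of bright pixels.

    A window of half-size 1.5 * radius_px around the approximate centre is
    thresholded with the isodata rule; the refined centre is the
    intensity-weighted centroid of the above-threshold pixels.  The estimate
    is equivariant under integer translation of the image.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    x0, y0 = approximate_centre
    half = 1.5 * radius_px
    c0, c1 = int(max(0, np.floor(x0 - half))), int(min(w, np.ceil(x0 + half) + 1))
    r0, r1 = int(max(0, np.floor(y0 - half))), int(min(h, np.ceil(y0 + half) + 1))
    window = image[r0:r1, c0:c1]
    if window.size == 0 or np.ptp(window) == 0:
        raise CentringError(f"empty or flat window around {approximate_centre}")
    thr = threshold_isodata(window)
    mask = window > thr
    if not mask.any():
        raise CentringError(f"no above-threshold pixels around {approximate_centre}")
    weights = window * mask
    total = weights.sum()
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (float((weights * xx).sum() / total), float((weights * yy).sum() / total))
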