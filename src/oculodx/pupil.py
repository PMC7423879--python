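"""Pupil segmentation and morphometry for grayscale eye frames.

Under infrared illumination the pupil is the darkest blob in the frame, so
segmentation is a global threshold (Otsu by default) followed by
8-connected labeling, keeping the largest dark component.  From the
segmented region nine raw parameters are measured: centroid abscissa and
ordinate, pixel area, minimum-area rotated bounding rectangle (area,
azimuth, aspect ratio), outer contour length, and left/right and
top/bottom area-symmetry ratios.

Conventions: row/col image coordinates, origin at the top-left, 0-based;
the bounding-rectangle azimuth is measured from the column axis,
counter-clockwise, reported in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .synthesis import EyeTrace

PARAMETER_NAMES = (
    "x", "y", "area", "mbr_area", "mbr_azimuth", "mbr_aspect_ratio",
    "contour_length", "lr_area_ratio", "tb_area_ratio",
)


@dataclass(frozen=True)
class PupilParams:
    """The nine raw morphometric parameters of one frame's pupil."""

    abscissa: float          # centroid column, px
    ordinate: float          # centroid row, px
    pupil_area: float        # px^2 (pixel count)
    mbr_area: float          # px^2, minimum-area rotated bounding rectangle
    mbr_azimuth: float       # degrees in [0, 180)
    mbr_aspect_ratio: float  # >= 1
    contour_length: float    # px
    lr_area_ratio: float     # left/right pixel-count ratio about the centroid
    tb_area_ratio: float     # top/bottom pixel-count ratio

    def as_row(self) -> dict[str, float]:
        return dict(zip(PARAMETER_NAMES, (
            self.abscissa, self.ordinate, self.pupil_area, self.mbr_area,
            self.mbr_azimuth, self.mbr_aspect_ratio, self.contour_length,
            self.lr_area_ratio, self.tb_area_ratio)))


class NoPupilError(ValueError):
    """Raised when a frame contains no segmentable pupil."""


def segment_pupil(image: np.ndarray,
                  threshold: float | None = None) -> np.ndarray:
    """Return the (n, 2) row/col coordinates of the largest dark component.

    With Otsu (the default) pixels at or below the computed threshold are
    candidate pupil pixels (Otsu reports the last intensity of the dark
    class); an explicit ``threshold`` keeps pixels strictly below it.  An
    empty array is returned when no dark pixel exists (uniform frame).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if threshold is None:
        if img.max() == img.min():
            return np.empty((0, 2), dtype=int)
        dark = img <= threshold_otsu(img)
    else:
        dark = img < threshold
    if not dark.any():
        return np.empty((0, 2), dtype=int)
    labels = cc_label(dark, connectivity=2)
    largest = max(regionprops(labels), key=lambda r: r.area)
    return largest.coords


def measure_pupil(region: np.ndarray) -> PupilParams:
    """Measure the nine pupil parameters of a pixel region.

    The minimum bounding rectangle is the minimum-area rotated rectangle of
    the region's convex hull (rotating calipers).  The symmetry ratios
    split the region about its centroid column/row, excluding pixels that
    sit exactly on the centroid line from both halves.
    """
    coords = np.asarray(region)
    if coords.size == 0:
        raise NoPupilError("no pupil in frame")
    rows = coords[:, 0].astype(float)
    cols = coords[:, 1].astype(float)
    area = float(len(coords))
    r_c, c_c = rows.mean(), cols.mean()

    mbr_area, azimuth, aspect = _min_bounding_rect(coords)
    contour = _contour_length(coords)

    left = float(np.count_nonzero(cols < c_c))
    right = float(np.count_nonzero(cols > c_c))
    top = float(np.count_nonzero(rows < r_c))
    bottom = float(np.count_nonzero(rows > r_c))
    lr = _sym_ratio(left, right)
    tb = _sym_ratio(top, bottom)

    return PupilParams(abscissa=c_c, ordinate=r_c, pupil_area=area,
                       mbr_area=mbr_area, mbr_azimuth=azimuth,
                       mbr_aspect_ratio=aspect, contour_length=contour,
                       lr_area_ratio=lr, tb_area_ratio=tb)


def _sym_ratio(a: float, b: float) -> float:
    if a == 0 and b == 0:
        return 1.0
    return a / b if b > 0 else np.inf


def _min_bounding_rect(coords: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area rotated rectangle of the pixel-center convex hull.

    The rectangle of pixel centers underestimates the physical extent by
    up to a half-pixel border, so the reported area is floored at the pixel
    count (a covering rectangle cannot be smaller than the region).
    """
    # shapely works in (x, y) = (col, row)
    hull_pts = [(c, r) for r, c in coords]
    rect = MultiPoint(hull_pts).convex_hull.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # 1- or 2-pixel degenerate region
        return float(len(coords)), 0.0, 1.0
    xy = np.asarray(rect.exterior.coords)[:4]
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    len1, len2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if len1 >= len2:
        long_edge, long_len, short_len = e1, len1, len2
    else:
        long_edge, long_len, short_len = e2, len2, len1
    mbr_area = max(float(len1 * len2), float(len(coords)))
    # Azimuth of the rectangle's long axis from the column axis toward the
    # row axis (counter-clockwise in the right-handed (col, row) frame),
    # in [0, 180).  The raw edge angle of a minimum-area rectangle is
    # ill-conditioned on pixelated regions (the rectangle pivots on hull
    # corner cuts), so the orientation is estimated from the second-order
    # central moments — the principal axis, which coincides with the
    # rectangle's long axis for any elongated convex region.
    x = coords[:, 1] - coords[:, 1].mean()
    y = coords[:, 0] - coords[:, 0].mean()
    mu20 = float((x * x).mean())
    mu02 = float((y * y).mean())
    mu11 = float((x * y).mean())
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        # isotropic region: fall back to the rectangle edge
        ang = np.degrees(np.arctan2(long_edge[1], long_edge[0])) % 180.0
    else:
        ang = np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02)) % 180.0
    aspect = float(long_len / short_len) if short_len > 0 else np.inf
    return mbr_area, float(ang), aspect


def _contour_length(coords: np.ndarray) -> float:
    """Perimeter of the traced outer boundary of the region."""
    from skimage.measure import perimeter

    rmin, cmin = coords.min(axis=0)
    mask = np.zeros(coords.max(axis=0) - (rmin, cmin) + 3, dtype=bool)
    mask[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = True
    return float(perimeter(mask, neighborhood=8))


def extract_trace(
    frames: Iterable[np.ndarray],
    subject_id: str = "S000",
    scheme_id: str = "horizontal_sweep",
    class_label: str = "C1",
    threshold: float | None = None,
) -> EyeTrace:
    """Measure every frame and assemble the per-frame parameter trace.

    Frames with no detectable pupil inherit the previous frame's
    parameters; a pupil-less prefix is back-filled from the first
    detection.  A stream with no pupil in any frame is an error.
    """
    rows: list[dict[str, float] | None] = []
    for img in frames:
        region = segment_pupil(img, threshold=threshold)
        try:
            rows.append(measure_pupil(region).as_row())
        except NoPupilError:
            rows.append(None)
    if not rows:
        raise ValueError("need at least one frame")
    if all(r is None for r in rows):
        raise NoPupilError("no pupil detected in any frame")

    # forward fill, then back-fill the leading gap
    last = None
    for i, r in enumerate(rows):
        if r is None and last is not None:
            rows[i] = dict(last)
        elif r is not None:
            last = r
    first = next(r for r in rows if r is not None)
    for i, r in enumerate(rows):
        if r is None:
            rows[i] = dict(first)

    data = pd.DataFrame(rows)
    data.insert(0, "frame", np.arange(len(rows)))
    return EyeTrace(subject_id=subject_id, scheme_id=scheme_id,
                    class_label=class_label, data=data)
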