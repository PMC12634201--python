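"""Perilesional quantification in a fixed region of interest.

Two standard read-outs around an injury site: cell density (centroids per
square millimetre inside a calibrated ROI, by default 500 × 500 µm centred
on the injury tip) and immunopositive-area fraction (percentage of ROI
pixels above an intensity threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgprep import binarize_otsu


class ROIGeometryError(ValueError):
    """ROI extends beyond the image bounds."""


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned ROI centred on a pixel coordinate.

    Edges are half-open: left/top inclusive, right/bottom exclusive, so
    tiled ROIs never double-count points.
    """

    center: tuple[float, float]  # (row, col) px
    width_um: float = 500.0
    height_um: float = 500.0
    pixel_size_um: float = 1.0

    def __post_init__(self):
        if self.width_um <= 0 or self.height_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("ROI dimensions and pixel size must be positive")

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6

    def bounds_px(self) -> tuple[float, float, float, float]:
        """(row0, col0, row1, col1), half-open."""
        h = self.height_um / self.pixel_size_um
        w = self.width_um / self.pixel_size_um
        r0 = self.center[0] - h / 2.0
        c0 = self.center[1] - w / 2.0
        return r0, c0, r0 + h, c0 + w

    def check_inside(self, shape: tuple[int, int]) -> None:
        r0, c0, r1, c1 = self.bounds_px()
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ROIGeometryError(
                f"ROI {self.bounds_px()} exceeds image bounds {shape}"
            )


def roi_cell_density(centroids, roi: ROISpec, image_shape=None) -> float:
    """Cells per mm²: centroids inside the half-open ROI over the ROI area.

    ``centroids`` is an (n, 2) array of (row, col) pixel positions or a
    DataFrame with centroid_row_px / centroid_col_px columns.
    """
    if hasattr(centroids, "columns"):
        pts = centroids[["centroid_row_px", "centroid_col_px"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if image_shape is not None:
        roi.check_inside(image_shape)
    r0, c0, r1, c1 = roi.bounds_px()
    inside = (pts[:, 0] >= r0) & (pts[:, 0] < r1) & (pts[:, 1] >= c0) & (pts[:, 1] < c1)
    return float(inside.sum()) / roi.area_mm2


def positive_area_fraction(image, roi: ROISpec, threshold="otsu") -> float:
    """Percentage of ROI pixels whose intensity exceeds the threshold.

    ``threshold`` is a fixed intensity (emulating a recorded manual
    threshold) or ``'otsu'``; the Otsu route makes the read-out invariant
    to affine intensity rescaling.
    """
    img = np.asarray(image)
    roi.check_inside(img.shape)
    r0, c0, r1, c1 = roi.bounds_px()
    patch = img[int(np.ceil(r0)) : int(np.ceil(r1)), int(np.ceil(c0)) : int(np.ceil(c1))]
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError("threshold must be a number or 'otsu'")
        thr, mask = binarize_otsu(patch)
    else:
        mask = patch > float(threshold)
    return 100.0 * float(mask.sum()) / mask.size
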