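"""Raw stack -> isolated single-cell binary masks.

The preprocessing chain mirrors standard fluorescence practice for
morphometry: maximum-intensity z-projection, large-scale background
subtraction (optionally followed by an annular FFT band-pass that enhances
contours), Otsu binarization, and connected-component isolation of
non-overlapping single cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops


class DegenerateImageError(ValueError):
    """Raised when an image cannot support the requested operation."""


@dataclass(frozen=True)
class CellMask:
    """A single isolated cell as a padded binary crop.

    Attributes
    ----------
    pixels : 2D bool array
        Foreground is exactly one 8-connected component and does not touch
        the crop border.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    offset : (int, int)
        (row, col) of the crop origin in the parent section image.
    """

    pixels: np.ndarray
    pixel_size_um: float
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not px.any():
            raise ValueError("CellMask foreground is empty")
        n_comp = cc_label(px, connectivity=2).max()
        if n_comp != 1:
            raise ValueError(f"CellMask must contain exactly one component, got {n_comp}")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2

    def with_pixel_size(self, pixel_size_um: float) -> "CellMask":
        return CellMask(self.pixels, pixel_size_um, self.offset)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack along z."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1 or stack.size == 0:
        raise ValueError("stack must be a nonempty (z, y, x) array")
    return stack.max(axis=0)


def correct_background(
    image: np.ndarray,
    gauss_sigma_um: float = 25.0,
    pixel_size_um: float = 1.0,
    fft_bandpass: bool = False,
    bandpass_low_um: float | None = None,
    bandpass_high_um: float | None = None,
) -> np.ndarray:
    """Subtract a large-scale Gaussian background estimate, clipping at zero.

    The background is the image smoothed with a Gaussian of ``gauss_sigma_um``
    (converted to pixels). When ``fft_bandpass`` is on, an annular band-pass
    in the Fourier domain is applied afterwards to sharpen contours; the band
    is given as spatial periods [bandpass_high_um, bandpass_low_um].
    """
    if gauss_sigma_um <= 0:
        raise ValueError("gauss_sigma_um must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    img = np.asarray(image, dtype=float)
    sigma_px = gauss_sigma_um / pixel_size_um
    background = gaussian(img, sigma=sigma_px, preserve_range=True)
    out = np.clip(img - background, 0.0, None)
    if fft_bandpass:
        low = bandpass_low_um if bandpass_low_um is not None else gauss_sigma_um
        high = bandpass_high_um if bandpass_high_um is not None else 2.0 * pixel_size_um
        out = _fft_bandpass(out, pixel_size_um, low_period_um=low, high_period_um=high)
        out = np.clip(out, 0.0, None)
    return out


def _fft_bandpass(
    image: np.ndarray, pixel_size_um: float, low_period_um: float, high_period_um: float
) -> np.ndarray:
    """Annular band-pass: keep spatial frequencies between the two periods."""
    h, w = image.shape
    fy = np.fft.fftfreq(h, d=pixel_size_um)
    fx = np.fft.fftfreq(w, d=pixel_size_um)
    fr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    lo_f = 1.0 / low_period_um  # cut frequencies below this (large structures)
    hi_f = 1.0 / high_period_um  # and above this (pixel noise)
    keep = (fr >= lo_f) & (fr <= hi_f)
    keep[0, 0] = True  # retain DC so intensities stay interpretable
    spec = np.fft.fft2(image)
    return np.real(np.fft.ifft2(spec * keep))


def binarize_otsu(image: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu threshold (maximizing between-class variance) and the bright mask."""
    img = np.asarray(image)
    if np.unique(img).size < 2:
        raise DegenerateImageError("Otsu threshold undefined for a constant image")
    thr = float(threshold_otsu(img))
    return thr, img > thr


@dataclass
class IsolationConfig:
    """Rules for selecting single cells from a binarized section."""

    min_area_um2: float = 50.0
    max_area_um2: float = 5000.0
    bbox_margin_px: int = 2
    pad_px: int = 2


def isolate_cells(
    mask: np.ndarray,
    n_target: int = 20,
    pixel_size_um: float = 1.0,
    config: IsolationConfig | None = None,
) -> list[CellMask]:
    """Isolate up to ``n_target`` non-overlapping single cells from a binary section.

    Components touching the image border or outside the configured area
    bounds are discarded; components whose (margin-expanded) bounding boxes
    overlap another component's box are discarded as overlapping. Among
    survivors the ``n_target`` largest are returned, ties broken by (row,
    col) of the bounding-box origin, each padded-cropped into its own
    :class:`CellMask`.
    """
    cfg = config or IsolationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("isolate_cells: empty mask, no cells to isolate")
        return []
    labeled = cc_label(mask, connectivity=2)
    props = regionprops(labeled)
    h, w = mask.shape
    px_area = pixel_size_um**2

    candidates = []
    for p in props:
        r0, c0, r1, c1 = p.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue  # touches border
        area_um2 = p.area * px_area
        if not (cfg.min_area_um2 <= area_um2 <= cfg.max_area_um2):
            continue
        candidates.append(p)

    # overlap rule: margin-expanded bounding boxes must be pairwise disjoint
    # against ALL components (including those already rejected), so merged or
    # touching cells never leak through
    m = cfg.bbox_margin_px
    survivors = []
    for p in candidates:
        r0, c0, r1, c1 = p.bbox
        box = (r0 - m, c0 - m, r1 + m, c1 + m)
        clash = False
        for q in props:
            if q.label == p.label:
                continue
            qr0, qc0, qr1, qc1 = q.bbox
            if box[0] < qr1 and qr0 < box[2] and box[1] < qc1 and qc0 < box[3]:
                clash = True
                break
        if not clash:
            survivors.append(p)

    if not survivors:
        warnings.warn("isolate_cells: no cells survived the selection rules")
        return []

    survivors.sort(key=lambda p: (-p.area, p.bbox[0], p.bbox[1]))
    out = []
    pad = cfg.pad_px
    for p in survivors[:n_target]:
        r0, c0, r1, c1 = p.bbox
        crop = np.zeros((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad), dtype=bool)
        crop[pad : pad + (r1 - r0), pad : pad + (c1 - c0)] = labeled[r0:r1, c0:c1] == p.label
        out.append(CellMask(crop, pixel_size_um, offset=(r0 - pad, c0 - pad)))
    return out


def prepare_section(
    stack: np.ndarray,
    pixel_size_um: float,
    n_target: int = 20,
    gauss_sigma_um: float = 25.0,
    fft_bandpass: bool = False,
    config: IsolationConfig | None = None,
) -> list[CellMask]:
    """Full preprocessing chain: project, background-correct, binarize, isolate."""
    proj = max_project(stack)
    corr = correct_background(
        proj, gauss_sigma_um=gauss_sigma_um, pixel_size_um=pixel_size_um, fft_bandpass=fft_bandpass
    )
    _, binary = binarize_otsu(corr)
    binary = ndimage.binary_opening(binary, structure=np.ones((3, 3)))
    return isolate_cells(binary, n_target=n_target, pixel_size_um=pixel_size_um, config=config)
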