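"""Single-cell morphometry: the 16-feature profile of a binary cell mask.

Features fall into four families:

* box-counting statistics — fractal dimension of the cell outline and
  gliding-box lacunarity, both over a geometric ladder of box sizes;
* convex-hull shape metrics — cell and hull area, perimeter, circularity
  (4πA/P²), density (cell/hull area) and roughness (cell/hull perimeter);
* skeleton statistics — total/max/mean process (branch) length and the
  straightness index (Euclidean over path length, averaged per branch),
  plus the Sholl profile of circle-crossing counts;
* soma geometry — cell-body area from the Shoelace formula on the soma
  contour polygon, with the soma found by morphological opening.

All lengths are in micrometres via the mask's pixel calibration; counts and
ratios are dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.measure import approximate_polygon, find_contours, label as cc_label
from skimage.morphology import disk, skeletonize
from sklearn.base import BaseEstimator, TransformerMixin

from .imgprep import CellMask

FEATURE_NAMES = [
    "fractal_dimension",
    "lacunarity",
    "cell_area_um2",
    "convex_hull_area_um2",
    "density",
    "cell_perimeter_um",
    "convex_hull_perimeter_um",
    "roughness",
    "convex_hull_circularity",
    "cell_circularity",
    "total_process_length_um",
    "max_process_length_um",
    "mean_process_length_um",
    "sholl_max_counts",
    "straightness",
    "cell_body_area_um2",
]


class InsufficientScaleError(ValueError):
    """Mask too small to support the box-size ladder."""


class DegenerateGeometryError(ValueError):
    """Mask too small or thin for a meaningful shape measurement."""


@dataclass(frozen=True)
class MorphometricProfile:
    fractal_dimension: float
    lacunarity: float
    cell_area_um2: float
    convex_hull_area_um2: float
    density: float
    cell_perimeter_um: float
    convex_hull_perimeter_um: float
    roughness: float
    convex_hull_circularity: float
    cell_circularity: float
    total_process_length_um: float
    max_process_length_um: float
    mean_process_length_um: float
    sholl_max_counts: int
    straightness: float
    cell_body_area_um2: float

    def as_series(self) -> pd.Series:
        return pd.Series(asdict(self))[FEATURE_NAMES]


@dataclass(frozen=True)
class ShollProfile:
    radii_um: np.ndarray
    counts: np.ndarray
    center: tuple[float, float]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_um, dtype=float)
        c = np.asarray(self.counts, dtype=int)
        if r.size and np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "radii_um", r)
        object.__setattr__(self, "counts", c)

    @property
    def max_counts(self) -> int:
        return int(self.counts.max()) if self.counts.size else 0


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, CellMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def _pixel_size(mask, pixel_size_um: float | None) -> float:
    if isinstance(mask, CellMask):
        return mask.pixel_size_um
    return 1.0 if pixel_size_um is None else float(pixel_size_um)


def default_box_sizes(shape: tuple[int, int]) -> np.ndarray:
    """Powers-of-two ladder from 2 px up to min(h, w) / 4.

    Small crops that cannot host 4 ladder points below min/4 extend the
    ladder up to min(h, w) / 2 so tightly cropped cells stay measurable.
    """
    def ladder(smax):
        sizes, s = [], 2
        while s <= smax:
            sizes.append(s)
            s *= 2
        return sizes

    sizes = ladder(min(shape) // 4)
    if len(sizes) < 4:
        sizes = ladder(min(shape) // 2)
    return np.asarray(sizes, dtype=int)


def box_count(pixels: np.ndarray, size: int) -> int:
    """Number of size×size grid boxes (anchored at the origin) containing foreground."""
    h, w = pixels.shape
    ph = (-h) % size
    pw = (-w) % size
    padded = np.pad(pixels, ((0, ph), (0, pw)))
    boxes = padded.reshape(padded.shape[0] // size, size, padded.shape[1] // size, size)
    return int(boxes.any(axis=(1, 3)).sum())


def outline(pixels: np.ndarray) -> np.ndarray:
    """Boundary pixel set: foreground minus its 4-connected erosion."""
    eroded = ndimage.binary_erosion(pixels, structure=ndimage.generate_binary_structure(2, 1))
    out = pixels & ~eroded
    return out if out.any() else pixels.copy()


def fractal_dimension(
    mask,
    mode: str = "outline",
    box_sizes=None,
) -> float:
    """Box-counting dimension: slope of log N(s) against log(1/s).

    By default N(s) counts boxes meeting the cell outline (boundary pixel
    set), the usual convention for contour complexity; ``mode='filled'``
    counts boxes meeting the full foreground.
    """
    px = _as_bool(mask)
    if not px.any():
        raise ValueError("empty mask")
    if mode not in ("outline", "filled"):
        raise ValueError("mode must be 'outline' or 'filled'")
    target = outline(px) if mode == "outline" else px
    sizes = default_box_sizes(px.shape) if box_sizes is None else np.asarray(box_sizes, dtype=int)
    if sizes.size < 4:
        raise InsufficientScaleError(
            f"box ladder has {sizes.size} points; at least 4 required (mask {px.shape})"
        )
    counts = np.array([box_count(target, int(s)) for s in sizes], dtype=float)
    slope, _ = np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)
    return float(slope)


def gliding_box_lacunarity(pixels: np.ndarray, size: int) -> float:
    """Λ(r) = var(m)/mean(m)² + 1 over all r×r gliding-box masses (stride 1)."""
    h, w = pixels.shape
    if size > min(h, w):
        raise InsufficientScaleError(f"box size {size} exceeds mask extent {pixels.shape}")
    # integral image for exact window sums
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(pixels, axis=0), axis=1, out=ii[1:, 1:])
    m = (
        ii[size:, size:]
        - ii[:-size, size:]
        - ii[size:, :-size]
        + ii[:-size, :-size]
    ).ravel()
    mean = m.mean()
    if mean == 0:
        return 1.0
    return float(np.var(m) / mean**2 + 1.0)


def lacunarity(mask, box_sizes=None) -> float:
    """Scalar gliding-box lacunarity: mean of Λ(r) over the box-size ladder."""
    px = _as_bool(mask)
    if not px.any():
        raise ValueError("empty mask")
    sizes = default_box_sizes(px.shape) if box_sizes is None else np.asarray(box_sizes, dtype=int)
    if sizes.size < 4:
        raise InsufficientScaleError(
            f"box ladder has {sizes.size} points; at least 4 required (mask {px.shape})"
        )
    return float(np.mean([gliding_box_lacunarity(px, int(s)) for s in sizes]))


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from the Shoelace formula, ½|Σ(x_i·y_{i+1} − x_{i+1}·y_i)|."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _outer_contour(pixels: np.ndarray) -> np.ndarray:
    """Longest 0.5-level contour of the (zero-padded) mask, in (row, col)."""
    padded = np.pad(pixels.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise DegenerateGeometryError("mask has no extractable contour")
    longest = max(contours, key=len)
    return longest - 1.0  # undo padding offset


def _polygon_length(contour: np.ndarray) -> float:
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def hull_and_shape_metrics(mask, pixel_size_um: float | None = None) -> dict:
    """Cell / convex-hull area, perimeter, circularity, density, roughness.

    Perimeters come from the subpixel 0.5-level contour polygon (not raw
    pixel-edge counts, which bias circularity of smooth shapes well below
    one); hull area and perimeter from the convex hull of that contour.
    """
    px = _as_bool(mask)
    cal = _pixel_size(mask, pixel_size_um)
    if px.sum() < 4:
        raise DegenerateGeometryError("mask too small for shape metrics")
    contour = _outer_contour(px)
    cell_area = float(px.sum()) * cal**2
    # 1-px Douglas-Peucker simplification removes the staircase excess that
    # otherwise biases circularity of smooth shapes well below 1
    cell_perim = _polygon_length(approximate_polygon(contour, tolerance=1.0)) * cal
    hull = ConvexHull(contour)
    hull_area = float(hull.volume) * cal**2  # 2D: volume is area
    hull_perim = float(hull.area) * cal  # 2D: area is perimeter
    return {
        "cell_area_um2": cell_area,
        "convex_hull_area_um2": hull_area,
        "density": cell_area / hull_area,
        "cell_perimeter_um": cell_perim,
        "convex_hull_perimeter_um": hull_perim,
        "roughness": cell_perim / hull_perim,
        "convex_hull_circularity": 4.0 * np.pi * hull_area / hull_perim**2,
        "cell_circularity": 4.0 * np.pi * cell_area / cell_perim**2,
    }


# ---------------------------------------------------------------------------
# skeleton statistics


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton; edge weights 1 or √2."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pts = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pts)
    for r, c in pts:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            q = (r + dr, c + dc)
            if q in pts:
                g.add_edge((r, c), q, weight=1.0 if dr * dc == 0 else np.sqrt(2.0))
    return g


def _branches(g: nx.Graph) -> list[tuple[list, float]]:
    """Decompose the skeleton graph into branches between nodes of degree ≠ 2.

    Returns (node path, path length in px) per branch; pure cycles with no
    junction are returned whole.
    """
    special = [n for n in g.nodes if g.degree(n) != 2]
    branches = []
    seen = set()
    for start in special:
        for nb in g.neighbors(start):
            edge = frozenset((start, nb))
            if edge in seen:
                continue
            path = [start, nb]
            length = g.edges[start, nb]["weight"]
            seen.add(edge)
            prev, cur = start, nb
            while g.degree(cur) == 2:
                nxt = next(n for n in g.neighbors(cur) if n != prev)
                e = frozenset((cur, nxt))
                if e in seen:
                    break
                length += g.edges[cur, nxt]["weight"]
                seen.add(e)
                path.append(nxt)
                prev, cur = cur, nxt
            branches.append((path, length))
    if not special:  # pure cycle
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            branches.append((list(comp), sub.size(weight="weight")))
    return branches


def skeleton_metrics(
    mask,
    pixel_size_um: float | None = None,
    prune_um: float = 2.0,
) -> dict:
    """Process-length statistics from the topology-preserving skeleton.

    The skeleton is decomposed into branches (paths between endpoints and
    junction pixels). Leaf branches shorter than ``prune_um`` that hang off
    a junction are treated as rasterization spurs and dropped. Branch length
    is the sum of inter-pixel steps (1 for 4-neighbour moves, √2 diagonal)
    times the pixel size; straightness is the unweighted mean over branches
    of endpoint Euclidean distance over path length.
    """
    px = _as_bool(mask)
    cal = _pixel_size(mask, pixel_size_um)
    skel = skeletonize(px)
    if skel.sum() < 2:
        warnings.warn("skeleton is empty or a single pixel; process lengths set to 0")
        return {
            "total_process_length_um": 0.0,
            "max_process_length_um": 0.0,
            "mean_process_length_um": 0.0,
            "straightness": 1.0,
            "skeleton": skel,
        }
    g = _skeleton_graph(skel)
    branches = _branches(g)
    prune_px = prune_um / cal
    kept = []
    for path, length in branches:
        a, b = path[0], path[-1]
        leaf_off_junction = (g.degree(a) == 1) != (g.degree(b) == 1) and (
            g.degree(a) >= 3 or g.degree(b) >= 3
        )
        if leaf_off_junction and length < prune_px:
            continue
        kept.append((path, length))
    if not kept:
        kept = branches
    lengths = np.array([l for _, l in kept]) * cal
    straight = []
    for path, length in kept:
        if length == 0:
            continue
        eucl = np.hypot(path[0][0] - path[-1][0], path[0][1] - path[-1][1])
        straight.append(min(eucl / length, 1.0))
    return {
        "total_process_length_um": float(lengths.sum()),
        "max_process_length_um": float(lengths.max()),
        "mean_process_length_um": float(lengths.mean()),
        "straightness": float(np.mean(straight)) if straight else 1.0,
        "skeleton": skel,
    }


def sholl_profile(
    mask,
    center: tuple[float, float] | None = None,
    step_um: float = 2.0,
    pixel_size_um: float | None = None,
    skeleton: np.ndarray | None = None,
) -> ShollProfile:
    """Crossings of the skeleton with concentric circles around the soma.

    For each radius r = step, 2·step, …, the count is the number of
    8-connected runs of skeleton pixels inside the annulus of half-width
    √2/2 px around the circle — i.e. the number of distinct processes
    crossing that circle.
    """
    px = _as_bool(mask)
    cal = _pixel_size(mask, pixel_size_um)
    skel = skeletonize(px) if skeleton is None else np.asarray(skeleton, dtype=bool)
    if center is None:
        center = tuple(np.array(np.nonzero(px)).mean(axis=1))
    if not (0 <= center[0] < px.shape[0] and 0 <= center[1] < px.shape[1]):
        raise ValueError(f"center {center} outside image {px.shape}")
    rows, cols = np.nonzero(skel)
    if rows.size == 0:
        return ShollProfile(np.empty(0), np.empty(0, dtype=int), center)
    dist_px = np.hypot(rows - center[0], cols - center[1])
    rmax_um = dist_px.max() * cal
    radii = np.arange(step_um, rmax_um + step_um, step_um)
    radii = radii[radii <= rmax_um + step_um / 2]
    half = np.sqrt(2.0) / 2.0  # annulus half-width in px: no crossing slips through
    counts = []
    for r_um in radii:
        r_px = r_um / cal
        sel = np.abs(dist_px - r_px) <= half
        ring = np.zeros_like(skel)
        ring[rows[sel], cols[sel]] = True
        counts.append(int(cc_label(ring, connectivity=2).max()))
    return ShollProfile(radii, np.asarray(counts, dtype=int), center)


def soma_mask(mask, opening_radius_um: float = 2.0, pixel_size_um: float | None = None) -> np.ndarray:
    """Soma = largest connected component after opening with a disc."""
    px = _as_bool(mask)
    cal = _pixel_size(mask, pixel_size_um)
    radius_px = max(1, int(round(opening_radius_um / cal)))
    opened = ndimage.binary_opening(px, structure=disk(radius_px))
    if not opened.any():
        raise DegenerateGeometryError(
            f"morphological opening (radius {opening_radius_um} um) erased the mask"
        )
    lab = cc_label(opened, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == largest


def cell_body_area(
    mask,
    opening_radius_um: float = 2.0,
    pixel_size_um: float | None = None,
) -> float:
    """Soma area via the Shoelace formula on the soma's outer contour polygon."""
    cal = _pixel_size(mask, pixel_size_um)
    soma = soma_mask(mask, opening_radius_um=opening_radius_um, pixel_size_um=cal)
    contour = _outer_contour(soma)
    return shoelace_area(contour) * cal**2


def morphometric_profile(
    mask: CellMask,
    sholl_step_um: float = 2.0,
    prune_um: float = 2.0,
    opening_radius_um: float = 2.0,
    fractal_mode: str = "outline",
) -> MorphometricProfile:
    """Compute the full 16-feature profile of one cell mask."""
    px = _as_bool(mask)
    cal = _pixel_size(mask, None)
    fd = fractal_dimension(mask, mode=fractal_mode)
    lac = lacunarity(mask)
    shape = hull_and_shape_metrics(mask)
    skel = skeleton_metrics(mask, prune_um=prune_um)
    soma = soma_mask(mask, opening_radius_um=opening_radius_um, pixel_size_um=cal)
    soma_centroid = tuple(np.array(np.nonzero(soma)).mean(axis=1))
    body = shoelace_area(_outer_contour(soma)) * cal**2
    sholl = sholl_profile(
        mask, center=soma_centroid, step_um=sholl_step_um, skeleton=skel["skeleton"]
    )
    return MorphometricProfile(
        fractal_dimension=fd,
        lacunarity=lac,
        total_process_length_um=skel["total_process_length_um"],
        max_process_length_um=skel["max_process_length_um"],
        mean_process_length_um=skel["mean_process_length_um"],
        straightness=skel["straightness"],
        sholl_max_counts=sholl.max_counts,
        cell_body_area_um2=body,
        **shape,
    )


class MorphometricExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: list of :class:`CellMask` -> 16-column feature frame.

    Parameters
    ----------
    sholl_step_um : float
        Radial spacing of the concentric Sholl circles.
    prune_um : float
        Skeleton spur-pruning threshold; leaf branches below this length
        hanging off a junction are discarded as rasterization artifacts.
    opening_radius_um : float
        Disc radius of the morphological opening that delineates the soma.
    fractal_mode : {'outline', 'filled'}
        Pixel set used for box counting.
    """

    def __init__(
        self,
        sholl_step_um: float = 2.0,
        prune_um: float = 2.0,
        opening_radius_um: float = 2.0,
        fractal_mode: str = "outline",
    ):
        self.sholl_step_um = sholl_step_um
        self.prune_um = prune_um
        self.opening_radius_um = opening_radius_um
        self.fractal_mode = fractal_mode

    def fit(self, X, y=None):
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for m in X:
            prof = morphometric_profile(
                m,
                sholl_step_um=self.sholl_step_um,
                prune_um=self.prune_um,
                opening_radius_um=self.opening_radius_um,
                fractal_mode=self.fractal_mode,
            )
            rows.append(prof.as_series())
        return pd.DataFrame(rows).reset_index(drop=True)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)
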