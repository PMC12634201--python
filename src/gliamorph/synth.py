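"""Seeded synthetic-data generators for every pipeline input.

The generators provide ground truth for the stages downstream of raw data:

* :func:`make_cell_image` — a z-stack of one labeled glial cell of a known
  morphology class (ramified: soma-centred branched tree; amoeboid: compact
  irregular blob; rod: elongated bipolar cell) over a low-frequency
  polynomial background with Gaussian noise, plus the exact binary mask.
* :func:`make_section` — a multi-cell field with a centroid/label table.
* :func:`make_trajectory` — an open-field walk of a tracked mouse: the hip
  follows a correlated random walk at a set speed, and the nose–hip–tail
  body-segment angle is cosine-modulated at a set gait frequency and
  amplitude, written in pose-table (x, y, likelihood) form.
* :func:`make_cq_table` — group-structured qPCR quantification-cycle tables
  with a known per-gene group effect against an unshifted reference gene.

Every generator is a pure function of its spec (same spec and seed give
bit-identical output); all randomness flows through one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .behavior import Trajectory

MORPH_CLASSES = ("ramified", "amoeboid", "rod")


class PackingError(RuntimeError):
    """Could not place the requested cells without overlap."""


class SizingError(ValueError):
    """Requested field too small to contain the cell."""


@dataclass(frozen=True)
class CellShapeSpec:
    """Generative parameters of one synthetic glial cell."""

    morph_class: str = "ramified"
    soma_radius_um: float = 4.0
    n_primary_processes: int = 5
    branch_prob: float = 0.08
    process_step_um: float = 2.0
    n_steps: int = 12
    elongation: float = 1.0
    noise_sd: float = 5.0
    pixel_size_um: float = 0.5
    field_um: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.morph_class not in MORPH_CLASSES:
            raise ValueError(f"morph_class must be one of {MORPH_CLASSES}")
        if self.soma_radius_um <= 0:
            raise ValueError("soma_radius_um must be positive")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def default_spec(morph_class: str, seed: int = 0, **overrides) -> CellShapeSpec:
    """Class-typical shape parameters.

    Ramified cells: small soma with several long branched processes.
    Amoeboid cells: large compact soma, no processes, mildly irregular
    outline. Rod cells: elongated soma with two short polar processes.
    """
    base = {
        "ramified": dict(
            soma_radius_um=4.0, n_primary_processes=5, branch_prob=0.08,
            process_step_um=2.5, n_steps=12, elongation=1.0,
        ),
        "amoeboid": dict(
            soma_radius_um=11.5, n_primary_processes=0, branch_prob=0.0,
            process_step_um=2.0, n_steps=0, elongation=1.05,
        ),
        "rod": dict(
            soma_radius_um=5.0, n_primary_processes=2, branch_prob=0.0,
            process_step_um=2.0, n_steps=4, elongation=3.5,
        ),
    }[morph_class]
    base.update(overrides)
    return CellShapeSpec(morph_class=morph_class, seed=seed, **base)


def _required_field_um(spec: CellShapeSpec) -> float:
    reach = spec.soma_radius_um * np.sqrt(spec.elongation) + spec.n_steps * spec.process_step_um
    return 2.0 * (reach + 4.0)


def _soma_polygon(spec: CellShapeSpec, rng: np.random.Generator, center_px) -> np.ndarray:
    """Irregular ellipse vertices (row, col) in pixels."""
    r_px = spec.soma_radius_um / spec.pixel_size_um
    a = r_px * np.sqrt(spec.elongation)
    b = r_px / np.sqrt(spec.elongation)
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    wobble = np.zeros_like(theta)
    if spec.morph_class == "amoeboid":
        # low-order radial harmonics: lumpy but convex-ish outline
        for k in range(2, 6):
            wobble += rng.normal(0, 0.035) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    tilt = rng.uniform(0, np.pi)
    x = a * np.cos(theta) * (1 + wobble)
    y = b * np.sin(theta) * (1 + wobble)
    rr = center_px[0] + x * np.sin(tilt) + y * np.cos(tilt)
    cc = center_px[1] + x * np.cos(tilt) - y * np.sin(tilt)
    return np.column_stack([rr, cc]), tilt


def _walk_process(
    rng: np.random.Generator,
    start: np.ndarray,
    angle0: float,
    n_steps: int,
    step_px: float,
    branch_prob: float,
    depth: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random-walk process confined to a ±45° sector of its launch angle.

    The sector confinement keeps sibling processes from merging, so every
    generated tip survives as a skeleton endpoint.
    """
    segments = []
    pos = start.astype(float)
    angle = angle0
    for i in range(n_steps):
        angle += rng.normal(0, np.deg2rad(18))
        angle = np.clip(angle, angle0 - np.pi / 4, angle0 + np.pi / 4)
        nxt = pos + step_px * np.array([np.sin(angle), np.cos(angle)])
        segments.append((pos.copy(), nxt.copy()))
        pos = nxt
        if depth < 2 and rng.random() < branch_prob and n_steps - i - 1 >= 2:
            side = rng.choice([-1.0, 1.0])
            sub_angle = np.clip(
                angle + side * np.deg2rad(35), angle0 - np.pi / 4, angle0 + np.pi / 4
            )
            segments += _walk_process(
                rng, pos, sub_angle, max(2, int((n_steps - i - 1) * 0.7)),
                step_px, branch_prob, depth + 1,
            )
    return segments


def make_cell_mask(spec: CellShapeSpec) -> np.ndarray:
    """Ground-truth binary mask of one cell (field sized from the spec)."""
    rng = np.random.default_rng(spec.seed)
    field_um = spec.field_um if spec.field_um is not None else _required_field_um(spec)
    if field_um < _required_field_um(spec):
        raise SizingError(
            f"field {field_um} um cannot contain soma + processes "
            f"({_required_field_um(spec):.1f} um required)"
        )
    n = int(round(field_um / spec.pixel_size_um))
    mask = np.zeros((n, n), dtype=bool)
    center = np.array([n / 2.0, n / 2.0])

    verts, tilt = _soma_polygon(spec, rng, center)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=mask.shape)
    mask[rr, cc] = True

    step_px = spec.process_step_um / spec.pixel_size_um
    r_px = spec.soma_radius_um / spec.pixel_size_um
    if spec.n_primary_processes > 0 and spec.n_steps > 0:
        proc = np.zeros_like(mask)
        if spec.morph_class == "rod":
            # poles of the long axis: major-axis direction is (sin t, cos t)
            # in (row, col), matching the process direction convention
            angles = [tilt, tilt + np.pi]
            launch_r = r_px * np.sqrt(spec.elongation) - 1
        else:
            offset = rng.uniform(0, 2 * np.pi)
            angles = [
                offset + 2 * np.pi * i / spec.n_primary_processes
                for i in range(spec.n_primary_processes)
            ]
            launch_r = r_px - 1
        for ang in angles[: spec.n_primary_processes]:
            start = center + launch_r * np.array([np.sin(ang), np.cos(ang)])
            for p, q in _walk_process(
                rng, start, ang, spec.n_steps, step_px, spec.branch_prob
            ):
                rr, cc = draw_line(
                    int(round(p[0])), int(round(p[1])), int(round(q[0])), int(round(q[1]))
                )
                keep = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
                proc[rr[keep], cc[keep]] = True
        proc = ndimage.binary_dilation(proc, structure=np.ones((3, 3)))
        mask |= proc
    return mask


def make_cell_image(spec: CellShapeSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """One synthetic cell: (z-stack, ground-truth mask, morphology label).

    The stack has three focal planes with different in-focus weights; each
    plane carries a low-frequency polynomial background and Gaussian noise,
    so maximum projection and background correction have real work to do.
    """
    mask = make_cell_mask(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    n = mask.shape[0]
    yy, xx = np.mgrid[0:n, 0:n] / n
    background = (
        30.0
        + 20.0 * rng.normal() * yy
        + 20.0 * rng.normal() * xx
        + 15.0 * rng.normal() * (yy - 0.5) * (xx - 0.5)
        + 10.0 * rng.normal() * (xx - 0.5) ** 2
    )
    cell = ndimage.gaussian_filter(mask.astype(float) * 200.0, sigma=0.7)
    weights = (0.6, 1.0, 0.7)
    stack = np.stack(
        [cell * w + background + rng.normal(0, spec.noise_sd, mask.shape) for w in weights]
    )
    return stack.astype(np.float32), mask, spec.morph_class


def _round_mix(n_cells: int, class_mix) -> list[int]:
    """Largest-remainder rounding of class proportions to integer counts."""
    mix = np.asarray(class_mix, dtype=float)
    mix = mix / mix.sum()
    raw = mix * n_cells
    counts = np.floor(raw).astype(int)
    rest = n_cells - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rest]] += 1
    return counts.tolist()


def make_section(
    n_cells: int,
    class_mix=(0.4, 0.4, 0.2),
    field_um: float = 500.0,
    template: CellShapeSpec | None = None,
    seed: int = 0,
    max_tries_per_cell: int = 200,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A multi-cell 2D section image plus its centroid/label ground-truth table.

    Cells are placed by rejection sampling so their bounding boxes (with a
    4-px margin) never overlap. ``class_mix`` gives the (ramified, amoeboid,
    rod) proportions, rounded by largest remainder to exactly ``n_cells``.
    """
    template = template or CellShapeSpec()
    rng = np.random.default_rng(seed)
    px = template.pixel_size_um
    n = int(round(field_um / px))
    image = np.zeros((n, n), dtype=float)
    section_mask = np.zeros((n, n), dtype=bool)

    counts = _round_mix(n_cells, class_mix)
    labels = [cls for cls, k in zip(MORPH_CLASSES, counts) for _ in range(k)]
    rng.shuffle(labels)

    margin = 4
    placed_boxes: list[tuple[int, int, int, int]] = []
    records = []
    for i, cls in enumerate(labels):
        spec = default_spec(cls, seed=int(rng.integers(2**31)), pixel_size_um=px,
                            noise_sd=0.0)
        cell_mask = make_cell_mask(spec)
        rows, cols = np.nonzero(cell_mask)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        crop = cell_mask[r0:r1, c0:c1]
        ch, cw = crop.shape
        if ch + 2 * margin >= n or cw + 2 * margin >= n:
            raise PackingError(f"field {field_um} um too small for a {cls} cell")
        for attempt in range(max_tries_per_cell):
            tr = int(rng.integers(margin, n - ch - margin))
            tc = int(rng.integers(margin, n - cw - margin))
            box = (tr - margin, tc - margin, tr + ch + margin, tc + cw + margin)
            if all(
                not (box[0] < b[2] and b[0] < box[2] and box[1] < b[3] and b[1] < box[3])
                for b in placed_boxes
            ):
                break
        else:
            raise PackingError(
                f"could not place cell {i} of {n_cells} after {max_tries_per_cell} tries"
            )
        placed_boxes.append(box)
        section_mask[tr : tr + ch, tc : tc + cw] |= crop
        cr, cc_ = np.nonzero(crop)
        records.append(
            {
                "cell_id": i,
                "morph_class": cls,
                "centroid_row_px": tr + cr.mean(),
                "centroid_col_px": tc + cc_.mean(),
                "centroid_row_um": (tr + cr.mean()) * px,
                "centroid_col_um": (tc + cc_.mean()) * px,
            }
        )

    yy, xx = np.mgrid[0:n, 0:n] / n
    background = 30.0 + 15.0 * rng.normal() * yy + 15.0 * rng.normal() * xx
    image = ndimage.gaussian_filter(section_mask.astype(float) * 200.0, sigma=0.7)
    image += background + rng.normal(0, template.noise_sd, image.shape)
    return image.astype(np.float32), pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# locomotion


@dataclass(frozen=True)
class WalkSpec:
    """Generative parameters of an open-field walk with cosine gait."""

    duration_s: float = 60.0
    fps: float = 30.0
    speed_cm_s: float = 8.0
    turn_sd_deg: float = 40.0
    gait_amplitude_deg: float = 12.0
    gait_freq_hz: float = 2.5
    arena_cm: float = 40.0
    angle_offset_deg: float = 150.0
    angle_noise_deg: float = 0.0
    keypoint_noise_px: float = 0.0
    dropout_rate: float = 0.01
    px_per_cm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 < self.gait_freq_hz < self.fps / 2:
            raise ValueError("gait_freq_hz must lie in (0, fps/2)")
        if self.arena_cm <= 0:
            raise ValueError("arena_cm must be positive")


def make_trajectory(spec: WalkSpec) -> Trajectory:
    """Correlated-random-walk hip path with a cosine-modulated body angle.

    The hip advances ``speed_cm_s / fps`` per frame along a heading with
    Gaussian per-frame increments (SD ``turn_sd_deg / sqrt(fps)``), reflecting
    specularly off the walls. The interior nose–hip–tail angle follows
    ``offset + A·cos(2π f t + φ)`` plus optional Gaussian noise; nose and
    tail-base keypoints are placed around the hip to realize that angle.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps)) + 1  # fencepost: n-1 intervals span duration_s
    dt = 1.0 / spec.fps
    step_cm = spec.speed_cm_s * dt
    wall = 2.0  # cm standoff for the body extent
    lo, hi = wall, spec.arena_cm - wall

    heading = rng.uniform(0, 2 * np.pi)
    pos = np.array([spec.arena_cm / 2.0, spec.arena_cm / 2.0])
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) * dt

    hip = np.empty((n, 2))
    headings = np.empty(n)
    for i in range(n):
        hip[i] = pos
        headings[i] = heading
        heading += np.deg2rad(rng.normal(0, spec.turn_sd_deg)) * np.sqrt(dt)
        u = np.array([np.cos(heading), np.sin(heading)])
        nxt = pos + step_cm * u
        if not lo <= nxt[0] <= hi:
            u[0] = -u[0]
        if not lo <= nxt[1] <= hi:
            u[1] = -u[1]
        heading = np.arctan2(u[1], u[0])
        pos = pos + step_cm * u

    angle = (
        spec.angle_offset_deg
        + spec.gait_amplitude_deg * np.cos(2 * np.pi * spec.gait_freq_hz * t + phase)
        + rng.normal(0, spec.angle_noise_deg, n)
    )
    delta = np.deg2rad(180.0 - angle)  # nose deviation from the body axis
    nose_len, tail_len = 3.0, 4.0  # cm
    nose = hip + nose_len * np.column_stack(
        [np.cos(headings + delta), np.sin(headings + delta)]
    )
    tail = hip - tail_len * np.column_stack([np.cos(headings), np.sin(headings)])
    centroid = (nose + hip + tail) / 3.0

    def conf(size):
        c = rng.beta(60, 1.2, size)
        drop = rng.random(size) < spec.dropout_rate
        c[drop] = rng.beta(1.5, 8.0, drop.sum())
        return c

    cols = {}
    for name, arr in (("nose", nose), ("hip", hip), ("tail_base", tail), ("centroid", centroid)):
        xy_px = arr * spec.px_per_cm
        noise = rng.normal(0, spec.keypoint_noise_px, xy_px.shape)
        cols[f"{name}_x"] = xy_px[:, 0] + noise[:, 0]
        cols[f"{name}_y"] = xy_px[:, 1] + noise[:, 1]
        cols[f"{name}_likelihood"] = conf(n)
    df = pd.DataFrame(cols)
    df.insert(0, "t", t)
    return Trajectory(data=df, fps=spec.fps, cm_per_px=1.0 / spec.px_per_cm)


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class CqSpec:
    """Group-structured quantification-cycle table parameters.

    ``group_effect_log2`` maps gene -> Cq shift (cycles) applied to the
    treated group; a −1-cycle shift doubles 2^(−ΔCq). The reference gene is
    never shifted.
    """

    n_per_group: int = 8
    genes: tuple = ("IL1b", "IL10", "iNOS", "GAPDH")
    reference_gene: str = "GAPDH"
    group_effect_log2: dict = field(default_factory=dict)
    cq_sd: float = 0.15
    n_replicates: int = 3
    sample_offset_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.reference_gene not in self.genes:
            raise ValueError("reference gene must be among genes")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.cq_sd < 0:
            raise ValueError("cq_sd must be nonnegative")
        if self.reference_gene in self.group_effect_log2 and self.group_effect_log2[
            self.reference_gene
        ]:
            raise ValueError("reference gene cannot carry a group effect")


def make_cq_table(spec: CqSpec) -> pd.DataFrame:
    """Tidy Cq table: sample, group, gene, replicate, cq, reference_gene flag."""
    rng = np.random.default_rng(spec.seed)
    baseline = {g: float(rng.uniform(20, 28)) for g in spec.genes}
    rows = []
    for group in ("control", "treated"):
        for s in range(spec.n_per_group):
            sample = f"{group}_{s + 1}"
            # per-sample RNA input offset: shifts every gene, cancels in dCq
            off = rng.normal(0, spec.sample_offset_sd) if spec.sample_offset_sd else 0.0
            for gene in spec.genes:
                mu = baseline[gene] + off
                if group == "treated":
                    mu += spec.group_effect_log2.get(gene, 0.0)
                for rep in range(spec.n_replicates):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep + 1,
                            "cq": mu + rng.normal(0, spec.cq_sd),
                            "reference_gene": gene == spec.reference_gene,
                        }
                    )
    return pd.DataFrame(rows)


def make_feature_blobs(
    n_per_cluster: int = 50,
    n_clusters: int = 4,
    n_features: int = 5,
    separation: float = 6.0,
    spread: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Well-separated isotropic Gaussian clusters in morphometric feature space.

    A controllable stand-in for populations of distinct cell types: cluster
    centres are drawn on a sphere of radius ``separation`` so pairwise centre
    distances are large relative to ``spread``.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_clusters, n_features))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    # push centres apart: repeated repulsion keeps the draw deterministic
    for _ in range(200):
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.linalg.norm(diff, axis=-1) + np.eye(n_clusters)
        force = (diff / dist[..., None] ** 2).sum(axis=1)
        centers += 0.1 * force
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= separation
    X = np.vstack(
        [rng.normal(c, spread, size=(n_per_cluster, n_features)) for c in centers]
    )
    y = np.repeat(np.arange(n_clusters), n_per_cluster)
    cols = [f"feature_{i + 1}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y
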