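"""Open-field locomotion, occupancy, gait and grip analysis from pose tables.

Works on per-frame keypoint trajectories in the pose-estimation CSV dialect
(three header rows: scorer / bodyparts / coords, with x, y, likelihood per
bodypart). Low-confidence frames are dropped and short gaps interpolated
before any kinematic quantity is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import median_filter

KEYPOINTS = ("nose", "hip", "tail_base", "centroid")


class EmptyTrajectoryError(ValueError):
    """No frames survive confidence filtering."""


@dataclass(frozen=True)
class Trajectory:
    """Per-frame keypoint coordinates with calibration.

    ``data`` columns: ``t`` (s) and, per keypoint, ``<kp>_x``, ``<kp>_y``
    (px) and ``<kp>_likelihood`` in [0, 1]. ``cm_per_px`` converts pixel
    coordinates to centimetres.
    """

    data: pd.DataFrame
    fps: float
    cm_per_px: float

    def __post_init__(self):
        if self.fps <= 0 or self.cm_per_px <= 0:
            raise ValueError("fps and cm_per_px must be positive")
        t = self.data["t"].to_numpy()
        if t.size >= 2 and not np.allclose(np.diff(t), 1.0 / self.fps, atol=1e-6):
            raise ValueError("t must increase in steps of 1/fps")
        for kp in self.keypoints:
            lk = self.data[f"{kp}_likelihood"].to_numpy()
            if np.any((lk < 0) | (lk > 1)):
                raise ValueError("likelihoods must lie in [0, 1]")

    @property
    def keypoints(self) -> list[str]:
        return [kp for kp in KEYPOINTS if f"{kp}_x" in self.data.columns]

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy_cm(self, keypoint: str) -> np.ndarray:
        return (
            self.data[[f"{keypoint}_x", f"{keypoint}_y"]].to_numpy(dtype=float)
            * self.cm_per_px
        )

    # -- pose-table CSV dialect ------------------------------------------
    def to_dlc_csv(self, path, scorer: str = "gliamorph") -> None:
        """Write the 3-header-row (scorer/bodyparts/coords) CSV dialect."""
        cols = pd.MultiIndex.from_tuples(
            [
                (scorer, kp, coord)
                for kp in self.keypoints
                for coord in ("x", "y", "likelihood")
            ],
            names=["scorer", "bodyparts", "coords"],
        )
        wide = pd.DataFrame(
            {
                (scorer, kp, coord): self.data[f"{kp}_{coord}"]
                for kp in self.keypoints
                for coord in ("x", "y", "likelihood")
            }
        )
        wide.columns = cols
        wide.index.name = None
        wide.to_csv(path)

    @classmethod
    def from_dlc_csv(cls, path, fps: float, cm_per_px: float) -> "Trajectory":
        wide = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        cols = {}
        for scorer, kp, coord in wide.columns:
            cols[f"{kp}_{coord}"] = wide[(scorer, kp, coord)].to_numpy(dtype=float)
        df = pd.DataFrame(cols)
        df.insert(0, "t", np.arange(len(df)) / fps)
        return cls(data=df, fps=fps, cm_per_px=cm_per_px)


def _filtered_xy(
    traj: Trajectory,
    keypoint: str,
    confidence_min: float = 0.9,
    max_gap_frames: int = 5,
) -> np.ndarray:
    """Keypoint path in cm with low-confidence frames interpolated.

    Frames below ``confidence_min`` are masked; gaps up to
    ``max_gap_frames`` are linearly interpolated, longer gaps are filled by
    nearest valid frame (flat extrapolation at the ends).
    """
    xy = traj.xy_cm(keypoint)
    lk = traj.data[f"{keypoint}_likelihood"].to_numpy()
    good = lk >= confidence_min
    if not good.any():
        raise EmptyTrajectoryError(
            f"no frames of '{keypoint}' reach confidence {confidence_min}"
        )
    idx = np.arange(len(xy))
    out = xy.copy()
    for d in range(2):
        out[~good, d] = np.interp(idx[~good], idx[good], xy[good, d])
    # long gaps: hold the last valid position instead of bridging linearly
    if max_gap_frames is not None:
        bad_runs = _runs(~good)
        for start, stop in bad_runs:
            if stop - start > max_gap_frames:
                left = start - 1
                right = stop if stop < len(xy) else None
                if left >= 0:
                    out[start:stop] = xy[left]
                elif right is not None:
                    out[start:stop] = xy[right]
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    edges = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


def locomotion_metrics(
    traj: Trajectory,
    keypoint: str = "hip",
    confidence_min: float = 0.9,
    smooth_frames: int = 3,
    raw_max: bool = False,
) -> dict:
    """Total distance (cm), average and maximum speed (cm/s).

    Distance and average speed come from the confidence-filtered path; the
    maximum speed is taken on positions median-smoothed over
    ``smooth_frames``, suppressing single-frame tracking spikes (``raw_max``
    reports the unsmoothed maximum instead).
    """
    xy = _filtered_xy(traj, keypoint, confidence_min=confidence_min)
    if len(xy) < 2:
        raise EmptyTrajectoryError("need at least 2 frames")
    # distance from the filtered path itself (exactly invariant to rigid
    # motion); only the max speed uses median smoothing, which guards that
    # single-frame statistic against tracking spikes
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    total = float(steps.sum())
    duration = (len(xy) - 1) / traj.fps
    if raw_max:
        speeds_max = float((steps * traj.fps).max())
    else:
        smoothed = median_filter(xy, size=(smooth_frames, 1), mode="nearest")
        speeds_max = float(
            (np.linalg.norm(np.diff(smoothed, axis=0), axis=1) * traj.fps).max()
        )
    return {
        "total_distance_cm": total,
        "average_speed_cm_s": total / duration,
        "max_speed_cm_s": speeds_max,
    }


def occupancy_map(
    traj: Trajectory,
    arena_cm: float,
    bins: int = 20,
    keypoint: str = "centroid",
    confidence_min: float = 0.9,
) -> np.ndarray:
    """Per-bin frame counts over the square arena; sums to the valid frames.

    Positions outside the arena are clipped into the edge bins, with a
    warning reporting how many frames were clipped.
    """
    lk = traj.data[f"{keypoint}_likelihood"].to_numpy()
    good = lk >= confidence_min
    if not good.any():
        raise EmptyTrajectoryError("no valid frames for occupancy")
    xy = traj.xy_cm(keypoint)[good]
    outside = np.any((xy < 0) | (xy > arena_cm), axis=1).sum()
    if outside:
        warnings.warn(f"occupancy_map: {outside} frames outside arena were clipped")
    xy = np.clip(xy, 0, np.nextafter(arena_cm, 0))
    edges = np.linspace(0, arena_cm, bins + 1)
    hist, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges, edges])
    return hist.astype(int)


def straight_walk_segments(
    traj: Trajectory,
    n_segments: int = 5,
    seg_s: float = 1.0,
    speed_min_cm_s: float = 3.0,
    turn_max_deg_s: float = 20.0,
    confidence_min: float = 0.9,
) -> list[tuple[int, int]]:
    """Non-overlapping 1-s windows of straight walking, as (start, stop) frames.

    A window qualifies when mean hip speed is at least ``speed_min_cm_s``
    and the net heading change does not exceed ``turn_max_deg_s × seg_s``.
    Qualifying windows are ranked by path straightness (net displacement
    over path length), ties broken by start time, and greedily selected
    without overlap.
    """
    xy = _filtered_xy(traj, "hip", confidence_min=confidence_min)
    win = int(round(seg_s * traj.fps))
    if win < 2 or len(xy) < win:
        return []
    scored = []
    for start in range(0, len(xy) - win + 1):
        seg = xy[start : start + win]
        steps = np.diff(seg, axis=0)
        path = np.linalg.norm(steps, axis=1).sum()
        speed = path / ((win - 1) / traj.fps)
        if speed < speed_min_cm_s:
            continue
        h0 = np.arctan2(*steps[0][::-1])
        h1 = np.arctan2(*steps[-1][::-1])
        dh = np.rad2deg(abs(np.angle(np.exp(1j * (h1 - h0)))))
        if dh > turn_max_deg_s * seg_s:
            continue
        net = np.linalg.norm(seg[-1] - seg[0])
        scored.append((net / path if path > 0 else 0.0, start))
    scored.sort(key=lambda s: (-s[0], s[1]))
    chosen: list[tuple[int, int]] = []
    for _, start in scored:
        window = (start, start + win)
        if all(window[1] <= a or b <= window[0] for a, b in chosen):
            chosen.append(window)
        if len(chosen) == n_segments:
            break
    if len(chosen) < n_segments:
        warnings.warn(
            f"only {len(chosen)} of {n_segments} straight-walk windows found"
        )
    return sorted(chosen)


def body_segment_angle(traj: Trajectory) -> np.ndarray:
    """Unsigned interior nose–hip–tail angle per frame, in degrees [0, 180]."""
    nose = traj.xy_cm("nose")
    hip = traj.xy_cm("hip")
    tail = traj.xy_cm("tail_base")
    u = nose - hip
    v = tail - hip
    cosang = (u * v).sum(axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))


@dataclass(frozen=True)
class GaitFit:
    amplitude_deg: float
    freq_hz: float
    phase_rad: float
    offset_deg: float
    r2: float
    segment: tuple[int, int]


def _cosine(t, a, f, phi, c):
    return a * np.cos(2 * np.pi * f * t + phi) + c


def fit_cosine(t: np.ndarray, angle: np.ndarray, fps: float,
               freq_bounds=(1.0, 8.0)) -> tuple[float, float, float, float, float]:
    """Least-squares A·cos(2πft+φ)+c fit, f seeded from the spectrum peak."""
    t = np.asarray(t, float)
    y = np.asarray(angle, float)
    # global initialization: coarse frequency grid, amplitude/phase/offset by
    # linear least squares at each candidate frequency (avoids the local
    # minima a single spectrum-peak start can fall into on short windows)
    best = None
    for f in np.arange(freq_bounds[0], freq_bounds[1] + 1e-9, 0.05):
        M = np.column_stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t), np.ones_like(t)])
        coef, res, *_ = np.linalg.lstsq(M, y, rcond=None)
        sse = float(((y - M @ coef) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, f, coef)
    _, f0, (ac, as_, c0) = best
    a0 = float(np.hypot(ac, as_))
    phi0 = float(np.arctan2(-as_, ac))
    p0 = [max(a0, 1e-3), f0, phi0, float(c0)]
    bounds = ([0.0, freq_bounds[0], -2 * np.pi, -np.inf],
              [np.inf, freq_bounds[1], 2 * np.pi, np.inf])
    popt, _ = optimize.curve_fit(_cosine, t, y, p0=p0, bounds=bounds, maxfev=10000)
    resid = y - _cosine(t, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return abs(popt[0]), popt[1], popt[2], popt[3], r2


def gait_amplitude(
    traj: Trajectory,
    windows: list[tuple[int, int]] | None = None,
    freq_bounds=(1.0, 8.0),
) -> tuple[list[GaitFit], float]:
    """Cosine-fit gait amplitude per straight-walk window and the per-mouse mean.

    The fitted quantity is the nose–hip–tail interior angle; its cosine
    amplitude indexes locomotor coordination. Windows that fail to converge
    are skipped with a diagnostic warning.
    """
    if windows is None:
        windows = straight_walk_segments(traj)
    angle = body_segment_angle(traj)
    t = traj.data["t"].to_numpy()
    fits = []
    for start, stop in windows:
        seg_t = t[start:stop] - t[start]
        seg_a = angle[start:stop]
        if np.ptp(seg_a) == 0:
            fits.append(GaitFit(0.0, freq_bounds[0], 0.0, float(seg_a[0]), 1.0, (start, stop)))
            continue
        try:
            a, f, phi, c, r2 = fit_cosine(seg_t, seg_a, traj.fps, freq_bounds)
        except RuntimeError as err:
            warnings.warn(f"gait fit failed on window {start}-{stop}: {err}")
            continue
        fits.append(GaitFit(a, f, phi, c, r2, (start, stop)))
    mean_amp = float(np.mean([f.amplitude_deg for f in fits])) if fits else float("nan")
    return fits, mean_amp


def grip_index(forces, body_weight_g: float) -> float:
    """Mean grip force over trials, normalized by body weight in grams."""
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0 or np.any(forces <= 0):
        raise ValueError("forces must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    return float(forces.mean() / body_weight_g)
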