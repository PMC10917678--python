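"""Markerless point tracking and windowed-peak scoring.

Behavioral videos (120 frames/s overhead recordings of neonatal mice) are
reduced to a scalar displacement trace in three steps: corner-like features
are seeded on the animal, tracked frame to frame with pyramidal
Lucas--Kanade optic flow, and the per-frame mean distance of the tracked
points from their pre-stimulus baseline position is taken as body
displacement in pixels.  The same peak-in-window primitive scores
displacement traces (peak in the 500 ms after a 50-ms air puff) and
membrane-potential traces (peak depolarization in a 10-ms window after an
uncaging pulse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi


@dataclass
class FrameStack:
    """Grayscale video: ``frames`` is (T, H, W), ``fps`` in frames/s.

    ``px_per_mm`` is optional spatial calibration taken from a ruler image
    recorded at the start of each session; displacements are reported in
    pixels regardless.
    """

    frames: np.ndarray
    fps: float
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T, H, W) with T >= 2")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class PointTrajectories:
    """Tracked positions, (P, T, 2) in (x, y) pixel units, 0-based.

    x increases rightward, y downward.  ``valid`` is (P, T); once a point
    drops out it stays invalid for the rest of the video.
    """

    positions: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must be (P, T, 2)")
        if self.positions.shape[0] < 1:
            raise ValueError("need at least one point")
        if self.valid.shape != self.positions.shape[:2]:
            raise ValueError("valid mask must be (P, T)")
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise ValueError("valid positions must be finite")


@dataclass
class TimeSeriesTrace:
    """Uniformly sampled scalar signal with a stimulus-onset index.

    ``values`` carries displacement in px or membrane potential in mV
    (``units`` tags which); ``valid`` marks samples where the quantity was
    measurable (e.g. at least one tracked point survived).
    """

    values: np.ndarray
    sampling_rate: float
    onset_index: int
    units: str = "px"
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.onset_index < self.values.size:
            raise ValueError("onset_index out of range")
        if self.valid is None:
            self.valid = np.ones(self.values.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match values")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid samples must be finite")


def seed_points(frame: np.ndarray, roi: tuple[int, int, int, int],
                n_points: int, min_distance: int = 1) -> np.ndarray:
    """Place up to ``n_points`` corner-like features inside ``roi``.

    ``roi`` is (x, y, w, h).  Features are Shi--Tomasi corners ranked by
    response; if the texture supports fewer than requested a warning is
    issued, and a completely untextured ROI is an error.

    Returns an (N, 2) array of (x, y) positions.
    """
    frame = np.asarray(frame, dtype=float)
    x0, y0, w, h = roi
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if x0 < 0 or y0 < 0 or x0 + w > frame.shape[1] or y0 + h > frame.shape[0]:
        raise ValueError("roi outside frame bounds")
    sub = frame[y0:y0 + h, x0:x0 + w]
    response = corner_shi_tomasi(sub)
    if sub.std() == 0 or response.max() <= 0:
        raise ValueError(f"no trackable texture in roi {roi}")
    peaks = corner_peaks(response, min_distance=min_distance,
                         threshold_rel=0.01, num_peaks=n_points)
    if peaks.shape[0] == 0:
        raise ValueError(f"no trackable features found in roi {roi}")
    if peaks.shape[0] < n_points:
        warnings.warn(f"only {peaks.shape[0]} of {n_points} requested "
                      f"features found in roi {roi}", stacklevel=2)
    # corner_peaks returns (row, col); convert to (x, y)
    return np.column_stack([peaks[:, 1] + x0, peaks[:, 0] + y0]).astype(float)


def _pyramid(img: np.ndarray, n_levels: int) -> list[np.ndarray]:
    levels = [img]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        if min(prev.shape) < 16:
            break
        sm = ndimage.gaussian_filter(prev, 1.0)
        levels.append(sm[::2, ::2])
    return levels


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_step(I: np.ndarray, J: np.ndarray, gy: np.ndarray, gx: np.ndarray,
             pts: np.ndarray, d0: np.ndarray, half: int,
             n_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid level of Lucas--Kanade for all points at once.

    ``pts`` (P, 2) in (x, y), ``d0`` the displacement guess; returns the
    refined displacement and the per-point normalized residual.
    """
    off = np.arange(-half, half + 1, dtype=float)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    oy = oy.ravel()
    ox = ox.ravel()
    P = pts.shape[0]
    base_y = pts[:, 1][:, None] + oy[None, :]
    base_x = pts[:, 0][:, None] + ox[None, :]

    Ip = _sample(I, base_y.ravel(), base_x.ravel()).reshape(P, -1)
    Iy = _sample(gy, base_y.ravel(), base_x.ravel()).reshape(P, -1)
    Ix = _sample(gx, base_y.ravel(), base_x.ravel()).reshape(P, -1)

    gxx = np.sum(Ix * Ix, axis=1)
    gxy = np.sum(Ix * Iy, axis=1)
    gyy = np.sum(Iy * Iy, axis=1)
    det = gxx * gyy - gxy * gxy
    ok = det > 1e-9
    inv = np.zeros((P, 2, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv[ok, 0, 0] = gyy[ok] / det[ok]
        inv[ok, 0, 1] = -gxy[ok] / det[ok]
        inv[ok, 1, 0] = -gxy[ok] / det[ok]
        inv[ok, 1, 1] = gxx[ok] / det[ok]

    d = d0.copy()
    for _ in range(n_iter):
        Jy = base_y + d[:, 1][:, None]
        Jx = base_x + d[:, 0][:, None]
        Jp = _sample(J, Jy.ravel(), Jx.ravel()).reshape(P, -1)
        It = Jp - Ip
        bx = np.sum(Ix * It, axis=1)
        by = np.sum(Iy * It, axis=1)
        d[:, 0] -= inv[:, 0, 0] * bx + inv[:, 0, 1] * by
        d[:, 1] -= inv[:, 1, 0] * bx + inv[:, 1, 1] * by

    Jy = base_y + d[:, 1][:, None]
    Jx = base_x + d[:, 0][:, None]
    Jp = _sample(J, Jy.ravel(), Jx.ravel()).reshape(P, -1)
    scale = np.std(Ip, axis=1) + 1e-6
    resid = np.mean(np.abs(Jp - Ip), axis=1) / scale
    return d, resid


def track_points(stack: FrameStack, points: np.ndarray, *,
                 n_levels: int = 3, window: int = 15,
                 n_iter: int = 5, residual_tol: float = 1.0,
                 border: int = 2) -> PointTrajectories:
    """Track ``points`` through the video with pyramidal Lucas--Kanade flow.

    3 pyramid levels and 15-px correlation windows by default.  Between
    successive frames each point's displacement is estimated coarse to
    fine by local least squares on the spatial gradients; positions
    accumulate frame to frame.  A point whose photometric residual exceeds
    ``residual_tol`` (patch mean absolute difference over patch s.d.) or
    that leaves the frame is marked invalid from that frame onward.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    T, H, W = stack.frames.shape
    if np.any(points[:, 0] < 0) or np.any(points[:, 0] > W - 1) or \
       np.any(points[:, 1] < 0) or np.any(points[:, 1] > H - 1):
        raise ValueError("points must lie inside the first frame")
    half = window // 2
    P = points.shape[0]
    positions = np.empty((P, T, 2))
    valid = np.ones((P, T), dtype=bool)
    positions[:, 0] = points

    def level_data(frame_idx: int):
        pyr = _pyramid(stack.frames[frame_idx], n_levels)
        grads = [np.gradient(lvl) for lvl in pyr]
        return pyr, grads

    pyr_I, grads_I = level_data(0)
    for t in range(1, T):
        pyr_J, _ = level_data(t)
        L = min(len(pyr_I), len(pyr_J))
        cur = positions[:, t - 1]
        d = np.zeros((P, 2))
        resid = np.zeros(P)
        for lvl in range(L - 1, -1, -1):
            s = 2.0 ** lvl
            d, resid = _lk_step(pyr_I[lvl], pyr_J[lvl],
                                grads_I[lvl][0], grads_I[lvl][1],
                                cur / s, d / s, half, n_iter)
            d = d * s
        new = cur + d
        out = ((new[:, 0] < border) | (new[:, 0] > W - 1 - border) |
               (new[:, 1] < border) | (new[:, 1] > H - 1 - border))
        bad = out | (resid > residual_tol) | ~valid[:, t - 1]
        valid[:, t] = ~bad
        positions[:, t] = np.where(bad[:, None], cur, new)
        pyr_I = pyr_J
        grads_I = [np.gradient(lvl) for lvl in pyr_J]
    return PointTrajectories(positions=positions, valid=valid)


def displacement_trace(traj: PointTrajectories,
                       baseline_window: tuple[int, int],
                       sampling_rate: float,
                       onset_index: int) -> TimeSeriesTrace:
    """Per-frame body displacement from tracked points, in pixels.

    Each point's reference is its mean position over ``baseline_window``
    (half-open frame range preceding stimulus onset); the trace value at a
    frame is the mean Euclidean distance of the valid points from their
    references.  Frames with no valid point are marked invalid.
    """
    b0, b1 = baseline_window
    if not (0 <= b0 < b1 <= traj.positions.shape[1]):
        raise ValueError("baseline_window out of range")
    if b1 > onset_index:
        raise ValueError("baseline_window must precede stimulus onset")
    base_valid = traj.valid[:, b0:b1]
    usable = base_valid.any(axis=1)
    if not usable.any():
        raise ValueError("no point is valid during the baseline window")
    pos = traj.positions[usable]
    bv = base_valid[usable][..., None]
    ref = np.sum(traj.positions[usable, b0:b1] * bv, axis=1) / bv.sum(axis=1)
    dist = np.linalg.norm(pos - ref[:, None, :], axis=2)
    v = traj.valid[usable]
    n_valid = v.sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(n_valid > 0,
                          np.sum(dist * v, axis=0) / np.maximum(n_valid, 1),
                          np.nan)
    trace_valid = n_valid > 0
    values = np.where(trace_valid, values, 0.0)
    return TimeSeriesTrace(values=values, sampling_rate=sampling_rate,
                           onset_index=onset_index, units="px",
                           valid=trace_valid)


def peak_in_window(trace: TimeSeriesTrace, *, onset_index: int | None = None,
                   window_duration: float = 0.5, cap: float | None = None,
                   fell_over: bool = False) -> float:
    """Maximum trace value in the half-open window after stimulus onset.

    The window covers samples (onset, onset + n] where
    n = floor(window_duration * sampling_rate); at 120 frames/s a 500-ms
    window is exactly 60 frames.  The onset sample itself is excluded.  If
    the animal fell over during the window and ``cap`` is given, the cap
    (106.383 px in the neonatal optical assay, the maximal displacement
    trackable before point occlusion) is returned instead.
    """
    onset = trace.onset_index if onset_index is None else onset_index
    n = int(np.floor(window_duration * trace.sampling_rate))
    if n < 1:
        raise ValueError("window shorter than one sample")
    if onset + n + 1 > trace.values.size:
        raise ValueError("window extends past end of trace")
    if fell_over:
        if cap is None:
            raise ValueError("fell_over set but no cap value given")
        return float(cap)
    sl = slice(onset + 1, onset + n + 1)
    if not trace.valid[sl].all():
        bad = np.nonzero(~trace.valid[sl])[0] + onset + 1
        raise ValueError(f"invalid samples inside scoring window: {bad.tolist()}")
    return float(np.max(trace.values[sl]))


def baseline_movement(trace: TimeSeriesTrace, *,
                      n_baseline_frames: int = 10) -> float:
    """Maximum displacement over the frames immediately preceding onset.

    The 10-frame pre-stimulus collection period is used to discard trials
    in which the animal was already moving.
    """
    onset = trace.onset_index
    if onset < n_baseline_frames:
        raise ValueError(
            f"need {n_baseline_frames} pre-stimulus frames, have {onset}")
    sl = slice(onset - n_baseline_frames, onset)
    if not trace.valid[sl].all():
        raise ValueError("invalid samples inside baseline window")
    return float(np.max(trace.values[sl]))
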