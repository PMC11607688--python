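"""Coarse-grained tissue flow from fluorescence time-lapses.

Pyramidal Kanade-Lucas-Tomasi (KLT) optical flow evaluated on a regular
grid: a 3-level Gaussian pyramid, a final window of 20 px (about one cell)
and a measurement every 10 px, preceded by rigid (translation + rotation)
registration of the time-lapse and followed by a 16-frame sliding temporal
average emitted every 4 frames.  Grid points whose structure tensor is
rank-deficient (textureless windows) are flagged invalid, never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation
from skimage.transform import pyramid_reduce, rotate

__all__ = [
    "FlowField",
    "RigidTransform",
    "flow_grid",
    "register_timelapse",
    "klt_flow",
    "time_average_flow",
]


@dataclass
class FlowField:
    """Velocity field on a regular grid, px/frame."""

    grid_row: np.ndarray          # (nr,) row coordinates of grid points
    grid_col: np.ndarray          # (nc,)
    v_row: np.ndarray             # (nr, nc)
    v_col: np.ndarray             # (nr, nc)
    valid: np.ndarray             # (nr, nc) bool
    frame: Optional[int] = None
    window: Optional[Tuple[int, int]] = None   # (start, stop) for time averages


@dataclass
class RigidTransform:
    angle_deg: float
    shift: Tuple[float, float]    # (row, col)
    flags: List[str] = field(default_factory=list)


def flow_grid(
    shape: Tuple[int, int], window_px: int = 20, step_px: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    """Measurement grid: every ``step_px`` pixels, inset by half a window."""
    half = window_px // 2
    rows = np.arange(half, shape[0] - half, step_px, dtype=float)
    cols = np.arange(half, shape[1] - half, step_px, dtype=float)
    return rows, cols


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

def _apply_rigid(frame: np.ndarray, t: RigidTransform) -> np.ndarray:
    out = rotate(frame, -t.angle_deg, preserve_range=True, order=1)
    return ndi.shift(out, t.shift, order=1, mode="constant", cval=0.0)


def register_timelapse(
    frames: np.ndarray,
    angle_range_deg: float = 10.0,
    angle_step_deg: float = 0.25,
    estimate_rotation: bool = True,
    upsample_factor: int = 10,
) -> Tuple[np.ndarray, List[RigidTransform]]:
    """Align every frame to the first by a rigid transform.

    Rotation is found by a coarse angular search (derotate candidate,
    score the phase-correlation residual), translation by subpixel phase
    correlation at the best angle.  A blank frame gets the identity
    transform and a warning.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with >= 2 frames")
    ref = frames[0]
    out = [ref.copy()]
    transforms = [RigidTransform(0.0, (0.0, 0.0))]
    angles = (
        np.arange(-angle_range_deg, angle_range_deg + angle_step_deg / 2, angle_step_deg)
        if estimate_rotation else np.array([0.0])
    )
    for i in range(1, frames.shape[0]):
        mov = frames[i]
        if mov.std() == 0:
            warnings.warn(f"frame {i} is blank; identity transform used", stacklevel=2)
            transforms.append(RigidTransform(0.0, (0.0, 0.0), flags=["blank_frame"]))
            out.append(mov.copy())
            continue
        mr = max(int(0.15 * ref.shape[0]), 1)
        mc = max(int(0.15 * ref.shape[1]), 1)
        crop = (slice(mr, -mr), slice(mc, -mc))
        best = (np.inf, 0.0, (0.0, 0.0))
        for ang in angles:
            cand = rotate(mov, -ang, preserve_range=True, order=1) if ang else mov
            shift, _, _ = phase_cross_correlation(
                ref, cand, upsample_factor=upsample_factor, normalization=None)
            aligned = ndi.shift(cand, shift, order=1, mode="constant", cval=0.0)
            # residual in the central crop scores the candidate angle
            mse = float(np.mean((aligned[crop] - ref[crop]) ** 2))
            if mse < best[0]:
                best = (mse, float(ang), (float(shift[0]), float(shift[1])))
        t = RigidTransform(best[1], best[2])
        transforms.append(t)
        out.append(_apply_rigid(mov, t))
    return np.stack(out), transforms


# ---------------------------------------------------------------------------
# pyramidal KLT
# ---------------------------------------------------------------------------

def _window_coords(center: np.ndarray, half: int) -> Tuple[np.ndarray, np.ndarray]:
    offs = np.arange(-half, half + 1, dtype=float)
    rr = center[0] + offs[:, None] + 0 * offs[None, :]
    cc = center[1] + 0 * offs[:, None] + offs[None, :]
    return rr, cc


def klt_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    pyramid_levels: int = 3,
    window_px: int = 20,
    step_px: int = 10,
    max_iter: int = 10,
    tol: float = 0.01,
    min_eig_ratio: float = 1e-3,
    frame: Optional[int] = None,
) -> FlowField:
    """Grid-sampled pyramidal Lucas-Kanade flow from ``frame_a`` to
    ``frame_b``.

    At each pyramid level (coarse to fine) and each grid point, the
    windowed least-squares flow equations are iterated to convergence;
    a point is invalid when the smallest structure-tensor eigenvalue falls
    below ``min_eig_ratio`` x the window's summed squared gradient at the
    finest level.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share one shape")
    if window_px < 3:
        raise ValueError("window_px must be >= 3")
    half = max(window_px // 2, 1)

    pyr_a = [a]
    pyr_b = [b]
    for _ in range(pyramid_levels - 1):
        pyr_a.append(pyramid_reduce(pyr_a[-1], downscale=2, preserve_range=True))
        pyr_b.append(pyramid_reduce(pyr_b[-1], downscale=2, preserve_range=True))

    rows, cols = flow_grid(a.shape, window_px, step_px)
    pts = np.array([(r, c) for r in rows for c in cols])
    v = np.zeros((len(pts), 2))
    valid = np.ones(len(pts), dtype=bool)

    for level in range(pyramid_levels - 1, -1, -1):
        scale = 2.0 ** level
        al, bl = pyr_a[level], pyr_b[level]
        gr, gc = np.gradient(al)
        for j, p in enumerate(pts):
            center = p / scale
            rr, cc = _window_coords(center, half)
            ix = ndi.map_coordinates(gr, [rr, cc], order=1, mode="nearest")
            iy = ndi.map_coordinates(gc, [rr, cc], order=1, mode="nearest")
            ia = ndi.map_coordinates(al, [rr, cc], order=1, mode="nearest")
            gxx = float((ix * ix).sum())
            gxy = float((ix * iy).sum())
            gyy = float((iy * iy).sum())
            trace = gxx + gyy
            lam_min = 0.5 * (trace - np.sqrt((gxx - gyy) ** 2 + 4 * gxy**2))
            if trace <= 0 or lam_min < min_eig_ratio * trace:
                if level == 0:
                    valid[j] = False
                continue
            G = np.array([[gxx, gxy], [gxy, gyy]])
            for _ in range(max_iter):
                ib = ndi.map_coordinates(
                    bl, [rr + v[j, 0] / scale, cc + v[j, 1] / scale],
                    order=1, mode="nearest")
                it = ib - ia
                rhs = -np.array([float((it * ix).sum()), float((it * iy).sum())])
                delta = np.linalg.solve(G, rhs)
                v[j] += delta * scale
                if np.hypot(*delta) < tol:
                    break
    v[~valid] = np.nan
    return FlowField(
        grid_row=rows,
        grid_col=cols,
        v_row=v[:, 0].reshape(len(rows), len(cols)),
        v_col=v[:, 1].reshape(len(rows), len(cols)),
        valid=valid.reshape(len(rows), len(cols)),
        frame=frame,
    )


def klt_flow_stack(
    frames: np.ndarray, **kwargs
) -> List[FlowField]:
    """Frame-to-frame flow for a whole registered stack."""
    frames = np.asarray(frames, dtype=float)
    return [
        klt_flow(frames[t], frames[t + 1], frame=t, **kwargs)
        for t in range(frames.shape[0] - 1)
    ]


# ---------------------------------------------------------------------------
# temporal averaging
# ---------------------------------------------------------------------------

def time_average_flow(
    fields: Sequence[FlowField],
    window_frames: int = 16,
    stride_frames: int = 4,
    min_valid_fraction: float = 0.5,
) -> List[FlowField]:
    """Sliding temporal mean of per-frame fields, emitted every
    ``stride_frames``; a grid point is valid in a window average when it is
    valid in at least ``min_valid_fraction`` of that window's frames."""
    if not fields:
        raise ValueError("no flow fields to average")
    g0 = fields[0]
    for f in fields[1:]:
        if not (np.array_equal(f.grid_row, g0.grid_row)
                and np.array_equal(f.grid_col, g0.grid_col)):
            raise ValueError("flow fields are on different grids")
    n = len(fields)
    if n < window_frames:
        warnings.warn(
            f"only {n} fields for a {window_frames}-frame window; emitting a "
            "single truncated-window average", stacklevel=2)
        starts = [0]
        window_frames = n
    else:
        starts = list(range(0, n - window_frames + 1, stride_frames))
    out = []
    for s in starts:
        chunk = fields[s: s + window_frames]
        vr = np.stack([f.v_row for f in chunk])
        vc = np.stack([f.v_col for f in chunk])
        ok = np.stack([f.valid for f in chunk])
        count = ok.sum(axis=0)
        valid = count >= np.ceil(min_valid_fraction * len(chunk))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mr = np.nanmean(np.where(ok, vr, np.nan), axis=0)
            mc = np.nanmean(np.where(ok, vc, np.nan), axis=0)
        mr[~valid] = np.nan
        mc[~valid] = np.nan
        out.append(FlowField(g0.grid_row.copy(), g0.grid_col.copy(), mr, mc,
                             valid, window=(s, s + window_frames)))
    return out
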