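"""Shape measures and anteroposterior (AP) fluorescence profiles.

A gastruloid mask is reduced to a midline — the ridge of the interior
distance transform, pruned to the longest end-to-end path, spline-smoothed
and extended to the mask boundary.  The midline anchors everything else:
local width (twice the distance-transform value), computational
straightening (resampling along midline normals) for second-moment
eccentricity, and AP intensity profiles (mean intensity along the normal at
every arc position).  Profiles are oriented so that the pole with the
highest reference-channel (T/brachyury) signal sits at normalized position
1 (posterior), rescaled to [0, 1], and intensity-normalized globally, per
group, or per channel maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import splev, splprep
from skimage import measure as skmeasure
from skimage.morphology import skeletonize

__all__ = [
    "Midline",
    "StraightenedShape",
    "RawProfile",
    "APProfile",
    "ProfileBand",
    "Kymograph",
    "measure_area_perimeter",
    "extract_midline",
    "straighten",
    "eccentricity",
    "ap_profile",
    "orient_and_normalize",
    "average_profiles",
    "kymograph",
    "average_kymographs",
    "multichannel_profile",
    "morphometrics_row",
]

# Ratio of midline length to mean width below which the AP axis is considered
# ill-defined (near-spherical aggregate); the sample is flagged, not rejected.
DEGENERATE_AXIS_RATIO = 1.5


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class Midline:
    """Ordered centerline polyline with per-vertex local width.

    vertices are (row, col) pixel-center coordinates at ~1 px arc spacing;
    arclength is the cumulative arc length (strictly increasing, starts at
    0); local_width is twice the interior distance-transform value.
    """

    vertices: np.ndarray          # (N, 2) float
    arclength: np.ndarray         # (N,) float
    local_width: np.ndarray       # (N,) float
    degenerate: bool = False
    flags: List[str] = field(default_factory=list)

    @property
    def length(self) -> float:
        return float(self.arclength[-1]) if len(self.arclength) else 0.0

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.local_width)) if len(self.local_width) else 0.0


@dataclass
class StraightenedShape:
    """Image/mask resampled on an (arc position x normal offset) grid."""

    grid: np.ndarray              # (n_arc, n_offset) float
    mask: Optional[np.ndarray]    # boolean, present when the input was binary
    a: Optional[float]            # semi-major axis of second-moment ellipse
    b: Optional[float]            # semi-minor axis
    arclength: float
    flags: List[str] = field(default_factory=list)


@dataclass
class RawProfile:
    """Per-sample raw AP profiles: arc position in px -> per-channel mean."""

    sample_id: str
    positions_px: np.ndarray
    channels: Dict[str, np.ndarray]
    group: str = ""


@dataclass
class APProfile:
    """Oriented, length- and intensity-normalized AP profile set."""

    sample_id: str
    positions: np.ndarray               # in [0, 1]; 0 = anterior, 1 = posterior
    intensities: Dict[str, np.ndarray]
    orientation_source: str
    intensity_norm: str                 # global | per_group | per_channel_max | none
    group_id: str = ""
    flipped: bool = False
    flags: List[str] = field(default_factory=list)


@dataclass
class ProfileBand:
    positions: np.ndarray
    mean: Dict[str, np.ndarray]
    sd: Dict[str, np.ndarray]
    n: int


@dataclass
class Kymograph:
    """Time x normalized-AP-position matrix of one channel's profile."""

    matrix: np.ndarray            # (T, n_positions), NaN rows = missing frames
    times: np.ndarray
    positions: np.ndarray
    channel: str
    flipped: bool = False


# ---------------------------------------------------------------------------
# area / perimeter
# ---------------------------------------------------------------------------

def measure_area_perimeter(
    mask: np.ndarray, pixel_size_um: Optional[float] = None
) -> Tuple[float, float]:
    """Area and perimeter of a single-component binary mask.

    Area is the pixel count times the pixel area; the perimeter uses the
    Crofton estimator (4 directions), which is accurate on smooth digitized
    outlines.  Units are um^2 / um when ``pixel_size_um`` is given, else
    px^2 / px.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    area_px = float(mask.sum())
    perim_px = float(skmeasure.perimeter_crofton(mask, directions=4))
    if pixel_size_um is not None:
        return area_px * pixel_size_um**2, perim_px * pixel_size_um
    return area_px, perim_px


# ---------------------------------------------------------------------------
# midline extraction
# ---------------------------------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    pts = set(map(tuple, np.argwhere(skel)))
    for p in pts:
        G.add_node(p)
        for dr, dc in _NBRS:
            q = (p[0] + dr, p[1] + dc)
            if q in pts:
                G.add_edge(p, q, weight=float(np.hypot(dr, dc)))
    return G


def _prune_branches(G: nx.Graph, edt: np.ndarray, prune_factor: float) -> None:
    """Iteratively remove endpoint branches shorter than prune_factor x the
    distance-transform value at their junction (skeleton spurs toward the
    boundary, e.g. rectangle corners)."""
    while True:
        deg = dict(G.degree)
        endpoints = [n for n, d in deg.items() if d == 1]
        removed = False
        for e in endpoints:
            if e not in G:
                continue
            path = [e]
            prev, cur = None, e
            while True:
                nbrs = [n for n in G.neighbors(cur) if n != prev]
                if dict(G.degree)[cur] >= 3 or not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
            if len(path) < 2 or dict(G.degree)[cur] < 3:
                continue
            blen = sum(
                np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(path, path[1:])
            )
            if blen < prune_factor * edt[cur]:
                G.remove_nodes_from(path[:-1])
                removed = True
        if not removed:
            return


def _longest_path(G: nx.Graph) -> List[Tuple[int, int]]:
    if G.number_of_nodes() == 0:
        return []
    if G.number_of_nodes() == 1:
        return list(G.nodes)
    deg = dict(G.degree)
    start = min((n for n, d in deg.items() if d == 1), default=min(G.nodes))
    far = max(
        nx.single_source_dijkstra_path_length(G, start, weight="weight").items(),
        key=lambda kv: (kv[1], kv[0]),
    )[0]
    lengths = nx.single_source_dijkstra_path_length(G, far, weight="weight")
    other = max(lengths.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return nx.dijkstra_path(G, far, other, weight="weight")


def _resample_polyline(pts: np.ndarray, step: float) -> np.ndarray:
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return pts[:1]
    grid = np.arange(0.0, s[-1] + step / 2, step)
    grid[-1] = min(grid[-1], s[-1])
    return np.column_stack([np.interp(grid, s, pts[:, 0]), np.interp(grid, s, pts[:, 1])])


def _extend_to_boundary(
    pts: np.ndarray, mask: np.ndarray, step: float = 0.5, max_steps: int = 10000
) -> np.ndarray:
    """Extend the polyline past both ends along the end tangents until the
    mask boundary is reached."""

    def inside(p: np.ndarray) -> bool:
        r, c = int(round(p[0])), int(round(p[1]))
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    def walk(p0: np.ndarray, tangent: np.ndarray) -> List[np.ndarray]:
        out, p = [], p0.copy()
        for _ in range(max_steps):
            p = p + tangent * step
            if not inside(p):
                break
            out.append(p.copy())
        return out

    t_end = pts[-1] - pts[-2]
    t_end = t_end / (np.linalg.norm(t_end) + 1e-12)
    t_start = pts[0] - pts[1]
    t_start = t_start / (np.linalg.norm(t_start) + 1e-12)
    head = walk(pts[0], t_start)[::-1]
    tail = walk(pts[-1], t_end)
    parts = [np.asarray(head).reshape(-1, 2), pts, np.asarray(tail).reshape(-1, 2)]
    return np.vstack([p for p in parts if len(p)])


def extract_midline(
    mask: np.ndarray,
    prune_factor: float = 1.5,
    spline_smooth: float = 2.0,
    step_px: float = 1.0,
) -> Midline:
    """Midline of a single-component mask via the interior distance transform.

    The skeleton of the mask approximates the ridge of the distance
    transform; spur branches shorter than ``prune_factor`` x the local width
    at their junction are pruned, the longest remaining end-to-end path is
    smoothed with a cubic smoothing spline, resampled at ``step_px`` arc
    steps and extended along the end tangents to the mask boundary.  Local
    width is twice the distance-transform value at each vertex.

    Near-circular masks, where the midline is shorter than
    ``DEGENERATE_AXIS_RATIO`` x the mean width, are flagged ``degenerate_axis``
    (the axis placement is then arbitrary) but still returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    edt = ndi.distance_transform_edt(mask)
    if edt.max() < 1.5:
        raise ValueError("mask is thinner than 3 px everywhere; no midline")

    skel = skeletonize(mask)
    G = _skeleton_graph(skel)
    _prune_branches(G, edt, prune_factor)
    path = _longest_path(G)

    flags: List[str] = []
    if len(path) < 4:
        # Near-point skeleton (disk-like mask): no usable axis direction.
        pts = np.asarray(path, dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            pts = np.asarray([np.argwhere(edt == edt.max())[0]], dtype=float)
        seg = np.hypot(*np.diff(pts, axis=0).T) if len(pts) > 1 else np.array([])
        arclength = np.concatenate([[0.0], np.cumsum(seg)]) if len(pts) > 1 else np.zeros(1)
        width = 2.0 * ndi.map_coordinates(edt, pts.T, order=1)
        return Midline(pts, arclength, width, degenerate=True,
                       flags=["degenerate_axis"])

    pts = np.asarray(path, dtype=float)
    # cubic smoothing spline on the ridge points, then uniform arc resampling
    k = 3 if len(pts) > 3 else 1
    try:
        tck, _ = splprep(pts.T, s=spline_smooth * len(pts), k=k)
        fine = np.asarray(splev(np.linspace(0, 1, max(len(pts) * 4, 16)), tck)).T
    except Exception:  # pragma: no cover - splprep degenerate fallback
        fine = pts
    fine = _resample_polyline(fine, step_px)
    ext = _extend_to_boundary(fine, mask)
    verts = _resample_polyline(ext, step_px)

    seg = np.hypot(*np.diff(verts, axis=0).T)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    width = 2.0 * ndi.map_coordinates(edt, verts.T, order=1)
    width = np.maximum(width, 1e-6)

    ml = Midline(verts, arclength, width, flags=flags)
    if ml.length < DEGENERATE_AXIS_RATIO * ml.mean_width:
        ml.degenerate = True
        ml.flags.append("degenerate_axis")
    return ml


# ---------------------------------------------------------------------------
# straightening and eccentricity
# ---------------------------------------------------------------------------

def _normals(vertices: np.ndarray) -> np.ndarray:
    t = np.gradient(vertices, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True) + 1e-12
    return np.column_stack([-t[:, 1], t[:, 0]])


def straighten(
    array: np.ndarray,
    midline: Midline,
    half_width_px: Optional[float] = None,
    order: Optional[int] = None,
) -> StraightenedShape:
    """Resample an image or mask along midline normals onto a rectangular
    (arc position x normal offset) grid.

    For a binary input the straightened mask and the semi-axes (a, b) of the
    ellipse with the same second moments are recorded; eccentricity is then
    ``sqrt(1 - (b/a)^2)``.
    """
    arr = np.asarray(array)
    is_mask = arr.dtype == bool
    data = arr.astype(float)
    if half_width_px is None:
        half_width_px = float(np.max(midline.local_width)) / 2.0 + 2.0
    if order is None:
        order = 1
    offsets = np.arange(-np.ceil(half_width_px), np.ceil(half_width_px) + 1)
    normals = _normals(midline.vertices)
    rows = midline.vertices[:, 0][:, None] + normals[:, 0][:, None] * offsets[None, :]
    cols = midline.vertices[:, 1][:, None] + normals[:, 1][:, None] * offsets[None, :]
    flags: List[str] = []
    if (rows.min() < 0 or cols.min() < 0 or rows.max() > data.shape[0] - 1
            or cols.max() > data.shape[1] - 1):
        flags.append("normals_clipped_to_frame")
        warnings.warn("straightening normals extend past the frame; clipped",
                      stacklevel=2)
    grid = ndi.map_coordinates(data, [rows, cols], order=order, mode="constant", cval=0.0)

    mask_s = a = b = None
    if is_mask:
        mask_s = grid >= 0.5
        if mask_s.any():
            props = skmeasure.regionprops(mask_s.astype(np.uint8))[0]
            a = props.axis_major_length / 2.0
            b = props.axis_minor_length / 2.0
    return StraightenedShape(grid, mask_s, a, b, arclength=midline.length, flags=flags)


def eccentricity(shape: StraightenedShape) -> float:
    """Eccentricity sqrt(1 - (b/a)^2) of the straightened mask's
    second-moment-equivalent ellipse; 0 for a circle, -> 1 for a line."""
    if shape.a is None or shape.b is None:
        raise ValueError("straightened shape has no mask; straighten a binary mask")
    if shape.a <= 0 or shape.b <= 0:
        shape.flags.append("degenerate_axes")
        return 1.0
    ratio = min(shape.b / shape.a, 1.0)
    return float(np.sqrt(1.0 - ratio**2))


# ---------------------------------------------------------------------------
# AP profiles
# ---------------------------------------------------------------------------

def ap_profile(
    channel: np.ndarray,
    mask: np.ndarray,
    midline: Midline,
    half_width_px: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Raw AP profile: at every midline arc position, the mean channel
    intensity along the normal direction, restricted to the mask interior.

    Returns (positions_px, values); positions whose normal does not
    intersect the mask are dropped with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if half_width_px is None:
        half_width_px = float(np.max(midline.local_width)) / 2.0 + 2.0
    offsets = np.arange(-np.ceil(half_width_px), np.ceil(half_width_px) + 1)
    normals = _normals(midline.vertices)
    rows = midline.vertices[:, 0][:, None] + normals[:, 0][:, None] * offsets[None, :]
    cols = midline.vertices[:, 1][:, None] + normals[:, 1][:, None] * offsets[None, :]
    # nearest-pixel sampling: averages actual pixel values and avoids
    # bilinear bleed of background intensity across the mask boundary
    vals = ndi.map_coordinates(channel, [rows, cols], order=0, mode="constant", cval=0.0)
    inmask = ndi.map_coordinates(mask.astype(float), [rows, cols], order=0,
                                 mode="constant", cval=0.0) >= 0.5
    counts = inmask.sum(axis=1)
    keep = counts > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} midline positions had empty normal-mask "
            "intersection and were dropped", stacklevel=2)
    with np.errstate(invalid="ignore"):
        prof = np.where(inmask, vals, 0.0).sum(axis=1)[keep] / counts[keep]
    return midline.arclength[keep], prof


def _posterior_mass_flip(positions: np.ndarray, ref: np.ndarray) -> Tuple[bool, bool]:
    """Decide whether to flip so the higher-mass half of the reference
    channel lies toward position 1.  Returns (flip, tie)."""
    span = positions[-1] - positions[0]
    if span <= 0:
        return False, True
    rel = (positions - positions[0]) / span
    first = float(ref[rel < 0.5].sum())
    second = float(ref[rel >= 0.5].sum())
    if first == second:
        return False, True
    return first > second, False


def orient_and_normalize(
    profiles: Sequence[RawProfile],
    reference_channel: str,
    length_grid_n: int = 100,
    intensity_norm: str = "global",
) -> List[APProfile]:
    """Orient raw profiles (posterior = highest reference-channel pole),
    rescale arc positions to [0, 1] on a common grid, and normalize
    intensities.

    intensity_norm:
      * ``global`` — each channel divided by its maximum over all profiles;
      * ``per_group`` — as global but within each profile's group;
      * ``per_channel_max`` — each profile's channel divided by its own max;
      * ``none`` — raw intensities.
    """
    if intensity_norm not in {"global", "per_group", "per_channel_max", "none"}:
        raise ValueError(f"unknown intensity_norm: {intensity_norm!r}")
    grid = np.linspace(0.0, 1.0, length_grid_n)
    out: List[APProfile] = []
    for rp in profiles:
        if reference_channel not in rp.channels:
            raise ValueError(
                f"reference channel {reference_channel!r} missing from sample "
                f"{rp.sample_id!r}")
        flip, tie = _posterior_mass_flip(rp.positions_px, rp.channels[reference_channel])
        span = rp.positions_px[-1] - rp.positions_px[0]
        rel = (rp.positions_px - rp.positions_px[0]) / (span if span > 0 else 1.0)
        flags = ["orientation_tie"] if tie else []
        chans = {}
        for name, vals in rp.channels.items():
            v = vals[::-1] if flip else vals
            r = (1.0 - rel[::-1]) if flip else rel
            chans[name] = np.interp(grid, r, v)
        out.append(APProfile(rp.sample_id, grid.copy(), chans, reference_channel,
                             intensity_norm, group_id=rp.group, flipped=flip,
                             flags=flags))

    channels = set().union(*(p.intensities.keys() for p in out)) if out else set()
    if intensity_norm == "per_channel_max":
        for p in out:
            for name in p.intensities:
                m = p.intensities[name].max()
                if m > 0:
                    p.intensities[name] = p.intensities[name] / m
    elif intensity_norm in {"global", "per_group"}:
        def norm_group(members: List[APProfile]) -> None:
            for name in channels:
                vals = [p.intensities[name] for p in members if name in p.intensities]
                if not vals:
                    continue
                m = max(float(v.max()) for v in vals)
                if m > 0:
                    for p in members:
                        if name in p.intensities:
                            p.intensities[name] = p.intensities[name] / m
        if intensity_norm == "global":
            norm_group(out)
        else:
            for g in sorted({p.group_id for p in out}):
                norm_group([p for p in out if p.group_id == g])
    return out


def average_profiles(profiles: Sequence[APProfile]) -> ProfileBand:
    """Per-position mean and sample (n-1) standard deviation over samples.

    Profiles are resampled to the first profile's grid if grids differ; a
    single profile yields an s.d. band of zeros.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    grid = profiles[0].positions
    channels = sorted(set().union(*(p.intensities.keys() for p in profiles)))
    mean: Dict[str, np.ndarray] = {}
    sd: Dict[str, np.ndarray] = {}
    for name in channels:
        rows = []
        for p in profiles:
            if name not in p.intensities:
                continue
            v = p.intensities[name]
            if len(p.positions) != len(grid) or not np.allclose(p.positions, grid):
                v = np.interp(grid, p.positions, v)
            rows.append(v)
        stack = np.vstack(rows)
        mean[name] = stack.mean(axis=0)
        sd[name] = stack.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(len(grid))
    return ProfileBand(grid.copy(), mean, sd, n=len(profiles))


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

def kymograph(
    frame_profiles: Sequence[Optional[RawProfile]],
    reference_channel: str,
    length_grid_n: int = 100,
    times: Optional[Sequence[float]] = None,
) -> Kymograph:
    """Stack per-frame oriented profiles into a time x AP-position matrix.

    The flip decision is taken once, from the final successfully profiled
    frame (where polarization is strongest), and applied to every frame so
    the axis cannot reverse between rows.  Frames with failed segmentation
    (None) become NaN rows.  Intensities are normalized to the movie-wide
    maximum.
    """
    grid = np.linspace(0.0, 1.0, length_grid_n)
    last = next((rp for rp in reversed(frame_profiles) if rp is not None), None)
    if last is None:
        raise ValueError("no valid frames in time-lapse")
    if reference_channel not in last.channels:
        raise ValueError(f"reference channel {reference_channel!r} missing")
    flip, _ = _posterior_mass_flip(last.positions_px, last.channels[reference_channel])

    rows = np.full((len(frame_profiles), length_grid_n), np.nan)
    for i, rp in enumerate(frame_profiles):
        if rp is None:
            continue
        span = rp.positions_px[-1] - rp.positions_px[0]
        rel = (rp.positions_px - rp.positions_px[0]) / (span if span > 0 else 1.0)
        v = rp.channels[reference_channel]
        if flip:
            v = v[::-1]
            rel = 1.0 - rel[::-1]
        rows[i] = np.interp(grid, rel, v)
    peak = np.nanmax(rows) if np.isfinite(rows).any() else 1.0
    if peak > 0:
        rows = rows / peak
    t = np.asarray(times, dtype=float) if times is not None else np.arange(len(frame_profiles), dtype=float)
    return Kymograph(rows, t, grid, reference_channel, flipped=flip)


def average_kymographs(kymos: Sequence[Kymograph]) -> Kymograph:
    """Average replicate kymographs (shared time/position grids) ignoring
    missing rows."""
    if not kymos:
        raise ValueError("no kymographs")
    shapes = {k.matrix.shape for k in kymos}
    if len(shapes) != 1:
        raise ValueError("kymograph grids differ; resample before averaging")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        avg = np.nanmean(np.stack([k.matrix for k in kymos]), axis=0)
    return Kymograph(avg, kymos[0].times.copy(), kymos[0].positions.copy(),
                     kymos[0].channel)


# ---------------------------------------------------------------------------
# multichannel (HCR) profiles
# ---------------------------------------------------------------------------

def multichannel_profile(
    channels: Dict[str, np.ndarray],
    masks: Dict[str, np.ndarray],
    reference_channel: str = "T",
    length_grid_n: int = 100,
    sample_id: str = "sample",
) -> APProfile:
    """Multichannel AP profile with the reference (T) channel defining the axis.

    The mask, midline and orientation are computed once from the reference
    channel; every channel is then sampled along that same axis (restricted
    to its own mask when provided, else the reference mask) and divided by
    its own maximum.
    """
    if reference_channel not in channels:
        raise ValueError(f"reference channel {reference_channel!r} not in image")
    if reference_channel not in masks:
        raise ValueError(f"no mask for reference channel {reference_channel!r}")
    ref_mask = np.asarray(masks[reference_channel], dtype=bool)
    midline = extract_midline(ref_mask)
    raw: Dict[str, np.ndarray] = {}
    positions = None
    for name, img in channels.items():
        m = np.asarray(masks.get(name, ref_mask), dtype=bool)
        pos, vals = ap_profile(img, m, midline)
        if positions is None or len(pos) < len(positions):
            positions = pos
        raw[name] = np.interp(positions, pos, vals) if len(pos) != len(positions) else vals
    rp = RawProfile(sample_id, positions, raw)
    (oriented,) = orient_and_normalize([rp], reference_channel,
                                       length_grid_n=length_grid_n,
                                       intensity_norm="per_channel_max")
    return oriented


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def morphometrics_row(
    mask: np.ndarray,
    pixel_size_um: Optional[float] = None,
    sample_id: str = "sample",
) -> Dict[str, object]:
    """One summary row per sample: area, perimeter, eccentricity, midline
    length, mean width and the degenerate-axis flag."""
    area, perim = measure_area_perimeter(mask, pixel_size_um)
    ml = extract_midline(mask)
    if ml.degenerate or len(ml.vertices) < 4:
        ecc = float("nan")
    else:
        ecc = eccentricity(straighten(np.asarray(mask, bool), ml))
    return {
        "sample_id": sample_id,
        "area": area,
        "perimeter": perim,
        "eccentricity": ecc,
        "midline_length": ml.length,
        "mean_width": ml.mean_width,
        "degenerate_flag": ml.degenerate,
    }
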