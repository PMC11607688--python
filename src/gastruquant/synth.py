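"""Synthetic fixtures with known ground truth for every pipeline stage.

Generates: (a) gastruloid-like images — a capsule silhouette swept along a
circular-arc midline, with AP-polarized fluorescence channels and a
textured brightfield channel; (b) time-lapses advected by a known velocity
field; (c) per-cell QC tables and normalized expression matrices with known
gating outcomes; (d) paired query/reference embeddings with a controllable
cluster-mixing parameter.  Every generator takes a single integer seed and
is bit-reproducible; every output carries enough ground truth (mask,
midline, profiles, velocity grid, pass flags, correspondences) to score the
downstream stages without re-deriving it.

Intensities are arbitrary units on the 16-bit microscopy range [0, 65535]
(kept as floats in memory; clipped to uint16 when written to TIFF).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .flow import FlowField, flow_grid
from .morphometrics import Midline
from .scqc import Embedding, ExpressionMatrix
from .segmentation import ImageSample

__all__ = [
    "ShapeSpec",
    "PolarizationSpec",
    "SyntheticSample",
    "FlowSpec",
    "TimelapseSample",
    "QCSpec",
    "CellTableResult",
    "ClusterSpec",
    "EmbeddingPair",
    "make_gastruloid_image",
    "make_timelapse",
    "make_cell_table",
    "make_embedding_pair",
    "default_cluster_spec",
    "sample_shape_spec",
    "write_sample",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    """Capsule silhouette swept along a circular-arc midline.

    ``bend_curvature`` is the midline curvature in 1/px (0 = straight);
    ``length_px`` is the midline (spine) arc length, so the pole-to-pole
    extent is length_px + width_px.
    """

    length_px: float
    width_px: float
    bend_curvature: float = 0.0
    orientation_deg: float = 0.0
    center: Optional[Tuple[float, float]] = None   # (row, col)

    def __post_init__(self) -> None:
        if self.length_px <= 0 or self.width_px <= 0:
            raise ValueError("length_px and width_px must be positive")
        if self.width_px > self.length_px:
            raise ValueError("width_px must not exceed length_px")


@dataclass(frozen=True)
class PolarizationSpec:
    """One fluorescence channel: mean intensity profile along the midline
    arc position s in [0, 1] plus additive Gaussian noise and a uniform
    background."""

    channel_name: str
    profile_fn: Callable[[np.ndarray], np.ndarray]
    noise_sd: float = 0.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        test = np.asarray(self.profile_fn(np.linspace(0, 1, 5)), dtype=float)
        if not np.isfinite(test).all():
            raise ValueError("profile_fn must be finite on [0, 1]")


@dataclass
class SyntheticSample:
    """Rendered image plus the generating ground truth."""

    image: ImageSample
    true_mask: np.ndarray
    true_midline: Midline
    true_profiles: Dict[str, Tuple[np.ndarray, np.ndarray]]   # channel -> (s, value)
    seed: int
    shape_spec: ShapeSpec = None
    channel_specs: Tuple[PolarizationSpec, ...] = ()
    arc_position_map: Optional[np.ndarray] = None   # s in [0,1] of nearest spine point

    def axis_profile(self, channel: str, n: int = 100) -> Tuple[np.ndarray, np.ndarray]:
        """Noise-free expected profile along the full measurable pole-to-pole
        axis (spine plus the two rounded caps, over which the intensity is
        flat at the end values)."""
        spec = next(c for c in self.channel_specs if c.channel_name == channel)
        L = self.shape_spec.length_px
        w = self.shape_spec.width_px
        total = L + w
        p = np.linspace(0.0, 1.0, n)
        s = np.clip(p * total - w / 2.0, 0.0, L) / L
        vals = spec.background_level + np.asarray(spec.profile_fn(s), dtype=float)
        return p, vals


@dataclass(frozen=True)
class FlowSpec:
    """Known advecting velocity field for a synthetic time-lapse."""

    field_fn: Callable[[np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]]
    n_frames: int = 2
    domain_labels: Optional[np.ndarray] = None   # per-pixel domain id

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass
class TimelapseSample:
    frames: np.ndarray                 # (T, H, W)
    true_fields: List[FlowField]       # ground truth on the flow grid, per step
    domain_grid: Optional[np.ndarray]  # (nr, nc) domain ids on the flow grid
    seed: int
    channel: str


@dataclass(frozen=True)
class QCSpec:
    """Distribution parameters for the per-cell QC variables (truncated
    normals; realistic for a filtered 10x run)."""

    ufc_mean: float = 4000.0
    ufc_sd: float = 1200.0
    mito_mean: float = 8.0
    mito_sd: float = 5.0
    trc_mean: float = 80_000.0
    trc_sd: float = 40_000.0


@dataclass
class CellTableResult:
    table: pd.DataFrame
    expression: ExpressionMatrix
    true_clusters: np.ndarray
    seed: int

    def qc_pass(self, thresholds) -> pd.Series:
        """Ground-truth pass flags under any threshold set (direct
        application of the strict inequalities to the generated values)."""
        from .scqc import qc_pass
        return qc_pass(self.table, thresholds)

    def true_gate(self, gene: str, pos_cutoff: float, neg_cutoff: float) -> np.ndarray:
        vals = self.expression.gene(gene)
        out = np.full(len(vals), "excluded", dtype=object)
        out[vals > pos_cutoff] = "positive"
        out[vals <= neg_cutoff] = "negative"
        return out


@dataclass(frozen=True)
class ClusterSpec:
    centroid: Tuple[float, ...]
    spread: float = 1.0


@dataclass
class EmbeddingPair:
    """Paired query/reference embeddings with known correspondence."""

    query: Embedding
    reference: Embedding
    mixing: Dict[str, float]
    seed: int
    expected_reference_cluster: Dict[str, str] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gastruloid images
# ---------------------------------------------------------------------------

def _spine_points(spec: ShapeSpec, frame_shape: Tuple[int, int],
                  step: float) -> Tuple[np.ndarray, np.ndarray]:
    """Midline spine sampled at ``step`` arc increments; returns (points
    (N,2) row/col, arc length values)."""
    L = spec.length_px
    s = np.arange(0.0, L + step / 2, step)
    s[-1] = min(s[-1], L)
    u = s - L / 2.0   # centered arc parameter
    k = spec.bend_curvature
    if abs(k) < 1e-12:
        x, y = u, np.zeros_like(u)
    else:
        R = 1.0 / k
        x = R * np.sin(u / R)
        y = R * (1.0 - np.cos(u / R))
    th = np.deg2rad(spec.orientation_deg)
    col = x * np.cos(th) - y * np.sin(th)
    row = x * np.sin(th) + y * np.cos(th)
    center = spec.center or (frame_shape[0] / 2.0, frame_shape[1] / 2.0)
    return np.column_stack([row + center[0], col + center[1]]), s


def _brightfield(mask: np.ndarray, rng: np.random.Generator,
                 level: float, noise_level: float) -> np.ndarray:
    """Brightfield look-alike: multi-octave smoothed-noise texture, a darker
    granular interior, and a dark rim at the aggregate boundary."""
    shape = mask.shape
    def octave(sigma: float) -> np.ndarray:
        f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
        sd = f.std()
        return f / sd if sd > 0 else f

    img = np.full(shape, level, dtype=float)
    img += 600.0 * noise_level * octave(2.0)
    img += 900.0 * noise_level * octave(8.0)
    # cellular granularity: fine-scale speckle inside the aggregate
    interior_tex = 2600.0 * noise_level * octave(1.2) + 1200.0 * noise_level * octave(4.0)
    img[mask] += interior_tex[mask] - 2500.0
    d_in = ndi.distance_transform_edt(mask)
    d_out = ndi.distance_transform_edt(~mask)
    rim = np.exp(-0.5 * (np.where(mask, d_in, d_out) / 2.5) ** 2)
    img -= 6000.0 * rim
    return np.clip(img, 0.0, 65535.0)


def make_gastruloid_image(
    shape: ShapeSpec,
    channels: Sequence[PolarizationSpec],
    seed: int,
    frame_shape: Tuple[int, int] = (360, 360),
    pixel_size_um: Optional[float] = None,
    brightfield: bool = True,
    bf_level: float = 30000.0,
    bf_noise_level: float = 1.0,
    sample_id: Optional[str] = None,
) -> SyntheticSample:
    """Render one gastruloid-like sample with full ground truth.

    Fluorescence intensity at a pixel inside the silhouette is
    ``background + profile_fn(s)`` where s in [0, 1] is the arc position of
    the nearest spine point, plus Gaussian noise; outside the silhouette
    only background and noise remain.  A silhouette touching the frame
    border raises a sizing error.
    """
    rng = np.random.default_rng(seed)
    dense, s_dense = _spine_points(shape, frame_shape, step=0.25)
    tree = cKDTree(dense)
    rr, cc = np.meshgrid(np.arange(frame_shape[0]), np.arange(frame_shape[1]),
                         indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = tree.query(pix)
    mask = (dist <= shape.width_px / 2.0).reshape(frame_shape)
    if not mask.any():
        raise ValueError("silhouette empty; check shape spec and frame size")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError(
            "silhouette touches the frame border; enlarge frame_shape or "
            "shrink the shape spec")
    L = shape.length_px
    s_map = (s_dense[idx] / L).reshape(frame_shape)

    chans: Dict[str, np.ndarray] = {}
    true_profiles: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    if brightfield:
        chans["BF"] = _brightfield(mask, rng, bf_level, bf_noise_level)
    s_grid = np.linspace(0.0, 1.0, 101)
    for spec in channels:
        img = np.full(frame_shape, spec.background_level, dtype=float)
        vals = np.asarray(spec.profile_fn(s_map[mask]), dtype=float)
        img[mask] += vals
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, frame_shape)
        chans[spec.channel_name] = np.clip(img, 0.0, 65535.0)
        true_profiles[spec.channel_name] = (
            s_grid.copy(),
            spec.background_level + np.asarray(spec.profile_fn(s_grid), dtype=float),
        )

    verts, s_v = _spine_points(shape, frame_shape, step=1.0)
    midline = Midline(
        vertices=verts,
        arclength=s_v,
        local_width=np.full(len(verts), float(shape.width_px)),
    )
    image = ImageSample(chans, pixel_size_um,
                        sample_id or f"synthetic_{seed}")
    return SyntheticSample(image, mask, midline, true_profiles, seed,
                           shape_spec=shape, channel_specs=tuple(channels),
                           arc_position_map=s_map)


def sample_shape_spec(rng: np.random.Generator,
                      frame_shape: Tuple[int, int] = (360, 360)) -> ShapeSpec:
    """Random realistic shape: ovoid to elongated, possibly bent."""
    length = float(rng.uniform(120, 210))
    width = float(rng.uniform(55, 90))
    curv = float(rng.uniform(0.0, 1.0 / 250.0))
    orient = float(rng.uniform(0, 180))
    return ShapeSpec(length, width, curv, orient,
                     center=(frame_shape[0] / 2.0, frame_shape[1] / 2.0))


# ---------------------------------------------------------------------------
# time-lapses
# ---------------------------------------------------------------------------

def _eval_field(field_fn, rr: np.ndarray, cc: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    try:
        vr, vc = field_fn(rr, cc)
        vr = np.broadcast_to(np.asarray(vr, dtype=float), rr.shape).copy()
        vc = np.broadcast_to(np.asarray(vc, dtype=float), rr.shape).copy()
    except Exception:
        f = np.vectorize(lambda r, c: field_fn(r, c), otypes=[float, float])
        vr, vc = f(rr, cc)
    return vr, vc


def make_timelapse(
    base: SyntheticSample,
    flow: FlowSpec,
    seed: int,
    channel: Optional[str] = None,
    noise_sd: float = 0.0,
    window_px: int = 20,
    step_px: int = 10,
) -> TimelapseSample:
    """Advect one channel of a synthetic sample by a known velocity field.

    Frame t+1 is frame t warped by ``field_fn`` (backward warp; exact for
    uniform fields) plus optional Gaussian noise.  The per-step ground-truth
    field is recorded on the same coarse grid the KLT stage measures on
    (every ``step_px`` px, half-window inset); per-frame displacements
    exceeding half the KLT window trigger a validity warning.
    """
    rng = np.random.default_rng(seed)
    if channel is None:
        channel = next(iter(base.image.channels))
    frame0 = np.asarray(base.image.channels[channel], dtype=float)
    H, W = frame0.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    vr, vc = _eval_field(flow.field_fn, rr, cc)
    speed = np.hypot(vr, vc).max()
    if speed > window_px / 2.0:
        warnings.warn(
            f"per-frame displacement {speed:.1f} px exceeds half the KLT "
            f"window ({window_px / 2:.0f} px); flow recovery may fail",
            stacklevel=2)

    frames = [frame0]
    for _ in range(flow.n_frames - 1):
        warped = ndi.map_coordinates(frames[-1], [rr - vr, cc - vc],
                                     order=1, mode="nearest")
        if noise_sd > 0:
            warped = warped + rng.normal(0.0, noise_sd, warped.shape)
        frames.append(warped)

    grows, gcols = flow_grid((H, W), window_px, step_px)
    gr, gc = np.meshgrid(grows, gcols, indexing="ij")
    gvr, gvc = _eval_field(flow.field_fn, gr, gc)
    true_fields = [
        FlowField(grows.copy(), gcols.copy(), gvr.copy(), gvc.copy(),
                  np.ones(gvr.shape, dtype=bool), frame=t)
        for t in range(flow.n_frames - 1)
    ]
    domain_grid = None
    if flow.domain_labels is not None:
        domain_grid = np.asarray(flow.domain_labels)[
            gr.astype(int), gc.astype(int)]
    return TimelapseSample(np.stack(frames), true_fields, domain_grid, seed,
                           channel)


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def make_cell_table(
    n_cells: int,
    qc_spec: QCSpec = QCSpec(),
    gene_spec: Optional[Dict[str, Dict[str, Tuple[float, float]]]] = None,
    seed: int = 0,
    cluster_proportions: Optional[Dict[str, float]] = None,
    dataset_id: str = "synthetic",
) -> CellTableResult:
    """Per-cell QC table and normalized expression matrix with known truth.

    ``gene_spec`` maps gene -> cluster -> (mean, sd) of normalized
    expression; cells are assigned to clusters by ``cluster_proportions``
    (default: uniform over the clusters named in gene_spec, or a single
    cluster "A").  The result's ``qc_pass``/``true_gate`` methods give the
    ground truth for any threshold set.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    gene_spec = gene_spec or {}
    cluster_names = sorted(
        {c for g in gene_spec.values() for c in g}) or ["A"]
    if cluster_proportions:
        names = sorted(cluster_proportions)
        p = np.array([cluster_proportions[n] for n in names], dtype=float)
        p /= p.sum()
        clusters = rng.choice(names, size=n_cells, p=p)
    else:
        clusters = rng.choice(cluster_names, size=n_cells)

    ufc = np.maximum(np.round(rng.normal(qc_spec.ufc_mean, qc_spec.ufc_sd, n_cells)), 0)
    mito = np.clip(rng.normal(qc_spec.mito_mean, qc_spec.mito_sd, n_cells), 0, 100)
    trc = np.maximum(np.round(rng.normal(qc_spec.trc_mean, qc_spec.trc_sd, n_cells)), 0)
    table = pd.DataFrame({
        "unique_feature_count": ufc,
        "mito_percent": mito,
        "total_rna_count": trc,
        "dataset_id": dataset_id,
        "cluster": clusters,
    })

    genes = sorted(gene_spec)
    vals = np.zeros((n_cells, len(genes)))
    for j, g in enumerate(genes):
        for cl, (mean, sd) in gene_spec[g].items():
            sel = clusters == cl
            draw = mean + (rng.normal(0.0, sd, int(sel.sum())) if sd > 0 else 0.0)
            vals[sel, j] = np.maximum(draw, 0.0)
    expr = ExpressionMatrix(vals, genes,
                            cell_ids=[f"cell_{i}" for i in range(n_cells)],
                            normalization="synthetic-normalized")
    return CellTableResult(table, expr, clusters, seed)


# ---------------------------------------------------------------------------
# embedding pairs
# ---------------------------------------------------------------------------

def default_cluster_spec(
    n_clusters: int = 4,
    n_dims: int = 50,
    centroid_scale: float = 1.3,
    spread: float = 1.0,
    seed: int = 0,
) -> Dict[str, ClusterSpec]:
    """Random well-separated cluster centroids in D dimensions."""
    rng = np.random.default_rng(seed)
    names = [f"C{i}" for i in range(n_clusters)]
    return {
        n: ClusterSpec(tuple(rng.normal(0.0, centroid_scale, n_dims)), spread)
        for n in names
    }


def make_embedding_pair(
    cluster_spec: Optional[Dict[str, ClusterSpec]] = None,
    n_query: Union[int, Dict[str, int]] = 150,
    n_reference: Union[int, Dict[str, int]] = 300,
    mixing: Union[float, Dict[str, float]] = 1.0,
    seed: int = 0,
    k_required: int = 30,
) -> EmbeddingPair:
    """Paired query/reference embeddings with a controllable overlap.

    Reference cells are drawn around each cluster centroid.  At mixing=1
    query cells share the reference centroid ("well-mixed"); as mixing
    decreases the query centroid is displaced toward the midpoint between
    its own and the next cluster's centroid, degrading both the labelling
    agreement and the unique-mapping fraction.  Reference clusters smaller
    than ``k_required`` are flagged, not truncated.
    """
    spec = cluster_spec or default_cluster_spec(seed=seed)
    names = sorted(spec)
    if len(next(iter(spec.values())).centroid) < 2:
        raise ValueError("embedding dimension must be >= 2")
    rng = np.random.default_rng(seed)

    def per_cluster(x, name):
        return x[name] if isinstance(x, dict) else x

    q_pts, q_lab, r_pts, r_lab = [], [], [], []
    mix_out: Dict[str, float] = {}
    flags: List[str] = []
    expected = {}
    for i, name in enumerate(names):
        cs = spec[name]
        centroid = np.asarray(cs.centroid, dtype=float)
        nxt = np.asarray(spec[names[(i + 1) % len(names)]].centroid, dtype=float)
        m = float(per_cluster(mixing, name))
        if not 0.0 <= m <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        mix_out[name] = m
        nq = int(per_cluster(n_query, name))
        nr = int(per_cluster(n_reference, name))
        if nq < 1 or nr < 1:
            raise ValueError("every cluster needs >= 1 query and reference cell")
        if nr < k_required:
            flags.append(f"{name}:reference_smaller_than_k({nr}<{k_required})")
        midpoint = (centroid + nxt) / 2.0
        q_centroid = m * centroid + (1.0 - m) * midpoint
        r_pts.append(rng.normal(0.0, cs.spread, (nr, len(centroid))) + centroid)
        q_pts.append(rng.normal(0.0, cs.spread, (nq, len(centroid))) + q_centroid)
        q_lab += [name] * nq
        r_lab += [name] * nr
        expected[name] = name
    query = Embedding(np.vstack(q_pts), np.asarray(q_lab), source="query")
    reference = Embedding(np.vstack(r_pts), np.asarray(r_lab), source="reference")
    return EmbeddingPair(query, reference, mix_out, seed,
                         expected_reference_cluster=expected, flags=flags)


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

def write_sample(sample: SyntheticSample, out_dir: str | Path) -> Path:
    """Write one sample as a multichannel TIFF (channels as pages, uint16)
    plus mask TIFF and a JSON ground-truth sidecar; returns the sidecar
    path."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = sample.image.id
    names = list(sample.image.channels)
    stack = np.stack([
        np.clip(sample.image.channels[n], 0, 65535).astype(np.uint16)
        for n in names
    ])
    img_path = out / f"{sid}.tif"
    tifffile.imwrite(img_path, stack, photometric="minisblack")
    mask_path = out / f"{sid}_mask.tif"
    tifffile.imwrite(mask_path, (sample.true_mask.astype(np.uint8) * 255))
    sidecar = {
        "sample_id": sid,
        "seed": sample.seed,
        "channels": names,
        "image": img_path.name,
        "mask": mask_path.name,
        "midline_vertices": sample.true_midline.vertices.tolist(),
        "midline_width": sample.true_midline.local_width.tolist(),
        "profiles": {
            ch: {"positions": pos.tolist(), "values": val.tolist()}
            for ch, (pos, val) in sample.true_profiles.items()
        },
        "shape": {
            "length_px": sample.shape_spec.length_px,
            "width_px": sample.shape_spec.width_px,
            "bend_curvature": sample.shape_spec.bend_curvature,
            "orientation_deg": sample.shape_spec.orientation_deg,
        },
    }
    sidecar_path = out / f"{sid}.json"
    sidecar_path.write_text(json.dumps(sidecar))
    return sidecar_path
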