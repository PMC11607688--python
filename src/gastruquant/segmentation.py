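"""Brightfield segmentation of gastruloid wide-field images.

The stage mirrors an annotate-few, segment-many workflow: images are
downsampled by a factor of two, a bank of ~350 per-pixel features
(difference of Gaussians, Gaussian gradient magnitudes, Laplacians of
Gaussian across a scale ladder, and DAISY descriptors) feeds a 3-class
multinomial logistic regression (background / inside / edge) trained on a
handful of manually annotated masks.  A watershed on the edge-probability
landscape provides an alternative mask; an automated plausibility policy
picks between the two (watershed preferred), with a manual mask always
winning.  The selected mask is morphologically smoothed and upsampled back
to full resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import daisy
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed
from skimage.transform import downscale_local_mean
from sklearn.linear_model import LogisticRegression

CLASS_NAMES = ("background", "inside", "edge")  # fixed order; ties -> lowest index

__all__ = [
    "CLASS_NAMES",
    "ImageSample",
    "FeatureBankConfig",
    "FeatureStack",
    "PixelClassifier",
    "MaskSelectionPolicy",
    "MaskResult",
    "downsample",
    "extract_features",
    "make_class_image",
    "train_pixel_classifier",
    "classify",
    "classifier_mask",
    "watershed_mask",
    "select_mask",
    "segment_image",
    "save_classifier",
    "load_classifier",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class ImageSample:
    """Multichannel 2D image; the unit of segmentation and profiling."""

    channels: Dict[str, np.ndarray]
    pixel_size_um: Optional[float] = None
    id: str = "sample"
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have differing shapes: {shapes}")
        for name, a in self.channels.items():
            a = np.asarray(a)
            if a.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if not np.isfinite(a).all():
                raise ValueError(f"channel {name!r} contains non-finite values")
            if a.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class FeatureBankConfig:
    """Scale ladder and DAISY geometry of the per-pixel feature bank.

    Defaults give 1 raw + 5 Gaussians + 4 DoG + 5 gradient magnitudes +
    5 LoG + (4 rings x 8 histograms + 1) x 10 orientations DAISY = 350
    features.
    """

    sigmas: Tuple[float, ...] = (1.0, 2.5, 5.0, 7.5, 10.0)
    daisy_radius: int = 15
    daisy_rings: int = 4
    daisy_histograms: int = 8
    daisy_orientations: int = 10
    include_raw: bool = True

    @property
    def n_features(self) -> int:
        n = len(self.sigmas) * 3 + (len(self.sigmas) - 1)
        if self.include_raw:
            n += 1
        n += (self.daisy_rings * self.daisy_histograms + 1) * self.daisy_orientations
        return n


@dataclass
class FeatureStack:
    data: np.ndarray               # (H, W, F) float32
    feature_names: List[str]
    downsample_factor: int = 1


@dataclass
class PixelClassifier:
    """Multinomial logistic regression over the feature bank.

    Probabilities are computed as softmax(X_std @ coef.T + intercept) with
    the training standardization baked in; class order is CLASS_NAMES.
    """

    coef: np.ndarray               # (3, F)
    intercept: np.ndarray          # (3,)
    feature_mean: np.ndarray       # (F,)
    feature_std: np.ndarray        # (F,)
    feature_names: List[str]
    bank_config: FeatureBankConfig
    edge_band_px: int
    training_sample_ids: List[str] = field(default_factory=list)
    seed: int = 0
    version: str = "1"

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = (features - self.feature_mean) / self.feature_std
        z = x @ self.coef.T + self.intercept
        z -= z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class MaskSelectionPolicy:
    """Automated plausibility checks standing in for visual inspection."""

    require_single_component: bool = True
    solidity_min: float = 0.7
    area_rel_range: Tuple[float, float] = (0.25, 4.0)


@dataclass
class MaskResult:
    mask: np.ndarray               # full-resolution boolean mask
    provenance: str                # classifier | watershed | manual
    prob_maps: Optional[np.ndarray] = None   # (3, h, w) at working resolution
    qc_flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample(image: ImageSample, factor: int = 2) -> ImageSample:
    """Reduce every channel by local averaging; the factor is recorded on
    the sample for later mask upsampling."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return image
    h, w = image.shape
    if factor > min(h, w):
        raise ValueError(f"factor {factor} exceeds image size {image.shape}")
    ch = {}
    for name, a in image.channels.items():
        a = np.asarray(a, dtype=float)[: h - h % factor, : w - w % factor]
        ch[name] = downscale_local_mean(a, (factor, factor))
    return ImageSample(ch, image.pixel_size_um, image.id,
                       downsample_factor=image.downsample_factor * factor)


# ---------------------------------------------------------------------------
# feature bank
# ---------------------------------------------------------------------------

def extract_features(
    image: np.ndarray, bank_config: FeatureBankConfig = FeatureBankConfig()
) -> FeatureStack:
    """Deterministic ~350-feature per-pixel bank on one 2D channel."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("extract_features expects a single 2D channel")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite pixels")

    feats: List[np.ndarray] = []
    names: List[str] = []
    if bank_config.include_raw:
        feats.append(img)
        names.append("raw")
    smoothed = {}
    for s in bank_config.sigmas:
        g = ndi.gaussian_filter(img, s)
        smoothed[s] = g
        feats.append(g)
        names.append(f"gauss_{s:g}")
    for s0, s1 in zip(bank_config.sigmas, bank_config.sigmas[1:]):
        feats.append(smoothed[s0] - smoothed[s1])
        names.append(f"dog_{s0:g}_{s1:g}")
    for s in bank_config.sigmas:
        feats.append(ndi.gaussian_gradient_magnitude(img, s))
        names.append(f"gradmag_{s:g}")
    for s in bank_config.sigmas:
        feats.append(ndi.gaussian_laplace(img, s))
        names.append(f"log_{s:g}")

    r = bank_config.daisy_radius
    # pad so DAISY descriptors exist for every pixel of the original frame
    padded = np.pad(img, r, mode="reflect")
    desc = daisy(
        padded,
        step=1,
        radius=r,
        rings=bank_config.daisy_rings,
        histograms=bank_config.daisy_histograms,
        orientations=bank_config.daisy_orientations,
    )
    desc = desc[: img.shape[0], : img.shape[1], :]
    n_daisy = desc.shape[-1]
    stack = np.concatenate(
        [np.stack(feats, axis=-1), desc.astype(np.float32)], axis=-1
    )
    names += [f"daisy_{i}" for i in range(n_daisy)]
    assert stack.shape[-1] == len(names) == bank_config.n_features
    return FeatureStack(stack.astype(np.float32), names)


# ---------------------------------------------------------------------------
# training and classification
# ---------------------------------------------------------------------------

def make_class_image(mask: np.ndarray, edge_band_px: int = 3) -> np.ndarray:
    """Convert a binary ground-truth mask into the 3-class image: edge is a
    band of ``edge_band_px`` on both sides of the mask boundary, inside is
    the mask minus the band, background the rest."""
    mask = np.asarray(mask, dtype=bool)
    d_in = ndi.distance_transform_edt(mask)
    d_out = ndi.distance_transform_edt(~mask)
    classes = np.zeros(mask.shape, dtype=np.uint8)
    classes[mask] = 1
    edge = (mask & (d_in <= edge_band_px)) | (~mask & (d_out <= edge_band_px))
    classes[edge] = 2
    return classes


def train_pixel_classifier(
    samples: Sequence[Tuple[np.ndarray, np.ndarray]],
    bank_config: FeatureBankConfig = FeatureBankConfig(),
    edge_band_px: int = 3,
    seed: int = 0,
    max_pixels_per_image: int = 8000,
    C: float = 1.0,
    sample_ids: Optional[Sequence[str]] = None,
) -> PixelClassifier:
    """Fit the 3-class pixel classifier from (image, binary mask) pairs.

    The binary annotation is expanded to background/inside/edge (see
    ``make_class_image``); up to ``max_pixels_per_image`` pixels per image
    are subsampled class-proportionally (deterministic in ``seed``),
    features standardized, and a multinomial logistic regression fitted.
    """
    if len(samples) == 0:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    class_seen = np.zeros(3, dtype=bool)
    for img, mask in samples:
        mask = np.asarray(mask, dtype=bool)
        classes = make_class_image(mask, edge_band_px)
        fs = extract_features(img, bank_config)
        x = fs.data.reshape(-1, fs.data.shape[-1])
        y = classes.ravel()
        for c in range(3):
            class_seen[c] |= bool((y == c).any())
        if len(y) > max_pixels_per_image:
            idx = rng.choice(len(y), size=max_pixels_per_image, replace=False)
            idx.sort()
            x, y = x[idx], y[idx]
        xs.append(x)
        ys.append(y)
    for c in range(3):
        if not class_seen[c]:
            raise ValueError(
                f"class {CLASS_NAMES[c]!r} absent from all training images")
    X = np.vstack(xs).astype(np.float64)
    y = np.concatenate(ys)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    model = LogisticRegression(C=C, max_iter=300, random_state=seed,
                               class_weight="balanced")
    model.fit((X - mean) / std, y)
    # reorder to the fixed class order in case a class index is missing order
    coef = np.zeros((3, X.shape[1]))
    intercept = np.zeros(3)
    for i, c in enumerate(model.classes_):
        coef[int(c)] = model.coef_[i]
        intercept[int(c)] = model.intercept_[i]
    return PixelClassifier(
        coef=coef,
        intercept=intercept,
        feature_mean=mean,
        feature_std=std,
        feature_names=_feature_names(bank_config),
        bank_config=bank_config,
        edge_band_px=edge_band_px,
        training_sample_ids=list(sample_ids) if sample_ids else [],
        seed=seed,
    )


def _feature_names(bank_config: FeatureBankConfig) -> List[str]:
    names: List[str] = []
    if bank_config.include_raw:
        names.append("raw")
    names += [f"gauss_{s:g}" for s in bank_config.sigmas]
    names += [f"dog_{a:g}_{b:g}" for a, b in zip(bank_config.sigmas, bank_config.sigmas[1:])]
    names += [f"gradmag_{s:g}" for s in bank_config.sigmas]
    names += [f"log_{s:g}" for s in bank_config.sigmas]
    n_daisy = (bank_config.daisy_rings * bank_config.daisy_histograms + 1) \
        * bank_config.daisy_orientations
    names += [f"daisy_{i}" for i in range(n_daisy)]
    return names


def classify(
    classifier: PixelClassifier, image: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel argmax label image and the three probability maps.

    Ties resolve to the lowest class index (background < inside < edge).
    Returns (labels (H, W) uint8, probs (3, H, W)).
    """
    fs = extract_features(image, classifier.bank_config)
    if fs.feature_names != classifier.feature_names:
        raise ValueError("feature bank does not match the classifier's training bank")
    probs = classifier.predict_proba(fs.data.reshape(-1, fs.data.shape[-1]))
    probs = probs.reshape(fs.data.shape[0], fs.data.shape[1], 3)
    labels = np.argmax(probs, axis=-1).astype(np.uint8)
    return labels, np.moveaxis(probs, -1, 0)


def classifier_mask(labels: np.ndarray, probs: Optional[np.ndarray] = None) -> np.ndarray:
    """Binary mask from the classifier output.

    The edge class straddles the object boundary symmetrically, so the mask
    is the region where P(inside) > P(background) (an edge-neutral
    decision) when probability maps are given, else the non-background
    labels; holes filled, largest connected component kept."""
    if probs is not None:
        m = probs[1] > probs[0]
    else:
        m = labels != 0
    m = ndi.binary_fill_holes(m)
    return _largest_component(m)


# ---------------------------------------------------------------------------
# watershed alternative
# ---------------------------------------------------------------------------

def watershed_mask(
    edge_prob: np.ndarray,
    inside_prob: np.ndarray,
    background_prob: np.ndarray,
    seed_threshold: float = 0.8,
) -> np.ndarray:
    """Watershed on the edge-probability landscape.

    Seeds: high-confidence inside regions (inside_prob > threshold) as one
    marker, high-confidence background components touching the frame border
    as the other.  Returns the inside basin.
    """
    shapes = {np.asarray(a).shape for a in (edge_prob, inside_prob, background_prob)}
    if len(shapes) != 1:
        raise ValueError("probability maps must share one shape")
    inside_seed = inside_prob > seed_threshold
    if not inside_seed.any():
        raise ValueError("no inside seed found: image appears unsegmentable")
    # spurious high-confidence blobs in the background would each seed a
    # basin; keep the dominant inside region as the single seed
    inside_seed = _largest_component(inside_seed)
    bg_seed = background_prob > seed_threshold
    if bg_seed.any():
        lab = cc_label(bg_seed)
        border = np.zeros_like(bg_seed)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touching = np.unique(lab[border & bg_seed])
        touching = touching[touching > 0]
        if touching.size:
            bg_seed = np.isin(lab, touching)
    if not bg_seed.any():
        bg_seed = np.zeros_like(inside_seed)
        bg_seed[0, :] = bg_seed[-1, :] = bg_seed[:, 0] = bg_seed[:, -1] = True
        bg_seed &= ~inside_seed
    markers = np.zeros(edge_prob.shape, dtype=np.int32)
    markers[bg_seed] = 2
    markers[inside_seed] = 1
    basins = watershed(np.asarray(edge_prob, dtype=float), markers)
    return basins == 1


# ---------------------------------------------------------------------------
# mask selection, smoothing, upsampling
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = cc_label(mask, return_num=True)
    if n <= 1:
        return mask.astype(bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _plausibility_flags(
    mask: np.ndarray, median_area: float, policy: MaskSelectionPolicy
) -> List[str]:
    flags = []
    if not mask.any():
        return ["empty"]
    lab, n = cc_label(mask, return_num=True)
    if policy.require_single_component and n != 1:
        flags.append(f"component_count={n}")
    props = regionprops(_largest_component(mask).astype(np.uint8))[0]
    if props.solidity < policy.solidity_min:
        flags.append(f"solidity={props.solidity:.2f}<{policy.solidity_min}")
    area = float(mask.sum())
    lo, hi = policy.area_rel_range
    if median_area > 0 and not (lo * median_area <= area <= hi * median_area):
        flags.append(f"area={area:.0f} outside [{lo}x, {hi}x] of median {median_area:.0f}")
    return flags


def smooth_mask(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Standard morphological smoothing: closing then opening with a disk,
    fill holes, keep the largest component."""
    se = disk(radius)
    m = ndi.binary_closing(np.asarray(mask, bool), structure=se)
    m = ndi.binary_opening(m, structure=se)
    m = ndi.binary_fill_holes(m)
    return _largest_component(m)


def upsample_mask(mask: np.ndarray, factor: int, full_shape: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """Block-upsample a working-resolution mask back to full resolution."""
    if factor == 1:
        up = mask.astype(bool)
    else:
        up = np.kron(mask.astype(bool), np.ones((factor, factor), dtype=bool))
    if full_shape is not None:
        out = np.zeros(full_shape, dtype=bool)
        r = min(full_shape[0], up.shape[0])
        c = min(full_shape[1], up.shape[1])
        out[:r, :c] = up[:r, :c]
        return out
    return up


def select_mask(
    watershed_m: np.ndarray,
    classifier_m: np.ndarray,
    manual: Optional[np.ndarray] = None,
    policy: MaskSelectionPolicy = MaskSelectionPolicy(),
    prob_maps: Optional[np.ndarray] = None,
    smooth_radius: int = 2,
    upsample_factor: int = 1,
    full_shape: Optional[Tuple[int, int]] = None,
) -> MaskResult:
    """Choose the final mask: manual always wins; otherwise the watershed
    mask when it passes the plausibility checks, else the classifier mask.
    The chosen mask is smoothed and upsampled to full resolution."""
    candidates = [m for m in (watershed_m, classifier_m, manual) if m is not None]
    areas = [float(np.asarray(m, bool).sum()) for m in candidates]
    median_area = float(np.median(areas)) if areas else 0.0

    flags: List[str] = []
    if manual is not None:
        chosen, provenance = np.asarray(manual, bool), "manual"
    else:
        ws_flags = _plausibility_flags(np.asarray(watershed_m, bool), median_area, policy)
        if not ws_flags:
            chosen, provenance = np.asarray(watershed_m, bool), "watershed"
        else:
            flags += [f"watershed:{f}" for f in ws_flags]
            cl_flags = _plausibility_flags(np.asarray(classifier_m, bool), median_area, policy)
            if not cl_flags:
                chosen, provenance = np.asarray(classifier_m, bool), "classifier"
            else:
                flags += [f"classifier:{f}" for f in cl_flags]
                raise ValueError(
                    "all candidate masks failed plausibility checks and no "
                    f"manual mask was provided: {flags}")
    final = smooth_mask(chosen, smooth_radius)
    final = upsample_mask(final, upsample_factor, full_shape)
    return MaskResult(final, provenance, prob_maps=prob_maps, qc_flags=flags)


def segment_image(
    classifier: PixelClassifier,
    image: ImageSample,
    brightfield_channel: str = "BF",
    factor: int = 2,
    manual: Optional[np.ndarray] = None,
    policy: MaskSelectionPolicy = MaskSelectionPolicy(),
    smooth_radius: int = 2,
) -> MaskResult:
    """Full single-image pipeline: downsample, classify the brightfield
    channel, build watershed and classifier masks, select, smooth and
    upsample."""
    if brightfield_channel not in image.channels:
        raise ValueError(f"channel {brightfield_channel!r} not in image {image.id!r}")
    small = downsample(image, factor)
    labels, probs = classify(classifier, small.channels[brightfield_channel])
    cmask = classifier_mask(labels, probs)
    try:
        wmask = watershed_mask(probs[2], probs[1], probs[0])
    except ValueError:
        wmask = np.zeros_like(cmask)
    manual_small = None
    if manual is not None:
        manual_small = downscale_local_mean(
            np.asarray(manual, float)[: image.shape[0] - image.shape[0] % factor,
                                      : image.shape[1] - image.shape[1] % factor],
            (factor, factor)) >= 0.5
    return select_mask(
        wmask, cmask, manual_small, policy=policy, prob_maps=probs,
        smooth_radius=smooth_radius, upsample_factor=factor,
        full_shape=image.shape,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_classifier(classifier: PixelClassifier, path: str | Path) -> None:
    """Persist the classifier as a versioned JSON bundle (weights, feature
    names, bank config)."""
    cfg = classifier.bank_config
    payload = {
        "version": classifier.version,
        "coef": classifier.coef.tolist(),
        "intercept": classifier.intercept.tolist(),
        "feature_mean": classifier.feature_mean.tolist(),
        "feature_std": classifier.feature_std.tolist(),
        "feature_names": classifier.feature_names,
        "edge_band_px": classifier.edge_band_px,
        "training_sample_ids": classifier.training_sample_ids,
        "seed": classifier.seed,
        "bank_config": {
            "sigmas": list(cfg.sigmas),
            "daisy_radius": cfg.daisy_radius,
            "daisy_rings": cfg.daisy_rings,
            "daisy_histograms": cfg.daisy_histograms,
            "daisy_orientations": cfg.daisy_orientations,
            "include_raw": cfg.include_raw,
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_classifier(path: str | Path) -> PixelClassifier:
    payload = json.loads(Path(path).read_text())
    cfg = payload["bank_config"]
    bank = FeatureBankConfig(
        sigmas=tuple(cfg["sigmas"]),
        daisy_radius=cfg["daisy_radius"],
        daisy_rings=cfg["daisy_rings"],
        daisy_histograms=cfg["daisy_histograms"],
        daisy_orientations=cfg["daisy_orientations"],
        include_raw=cfg["include_raw"],
    )
    return PixelClassifier(
        coef=np.asarray(payload["coef"]),
        intercept=np.asarray(payload["intercept"]),
        feature_mean=np.asarray(payload["feature_mean"]),
        feature_std=np.asarray(payload["feature_std"]),
        feature_names=list(payload["feature_names"]),
        bank_config=bank,
        edge_band_px=payload["edge_band_px"],
        training_sample_ids=payload["training_sample_ids"],
        seed=payload["seed"],
        version=payload["version"],
    )
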