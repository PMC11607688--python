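# Methods

This note documents the models, parameter choices and numerical details
behind each stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Synthetic gastruloids

**Silhouette model.** An aggregate is a capsule: the set of pixels within
`width_px / 2` of a spine, where the spine is a circular arc of length
`length_px` and curvature `bend_curvature` (1/px; 0 = straight), rotated by
`orientation_deg` about the frame center. This covers the observed ovoid →
elongated → bent shape progression without any biophysical simulation. The
spine is parametrized by arc length, so the recorded midline truth has
exactly the specified length; the measurable pole-to-pole axis is
`length_px + width_px` because the rounded caps extend half a width past
each spine end. A silhouette touching the frame border raises an error
rather than silently truncating the shape.

**Fluorescence.** Each reporter channel is
`background + profile_fn(s) + N(0, noise_sd²)` inside the mask and
`background + noise` outside, where `s ∈ [0, 1]` is the arc position of the
nearest spine point. Ground truth is recorded twice: `true_profiles` holds
`background + profile_fn` on the spine grid (the generating gradient), and
`SyntheticSample.axis_profile()` evaluates the expectation along the full
pole-to-pole axis — constant over the caps — which is what a
midline-based measurement can recover. Recovery tests compare against the
axis form.

**Brightfield.** Multi-octave smoothed Gaussian noise for the background,
a 2500-intensity-unit darker interior with fine-grained speckle (cellular
granularity, correlation length ≈ 1 px), and a Gaussian-profile dark rim at
the boundary. This is a stand-in chosen to look and segment like real
brightfield data — interior texture statistics differ from background, and
the rim carries the edge signal — not a calibrated optical model. Noise
amplitudes scale with a single `bf_noise_level` knob (default 1, the
benchmark condition). Intensities are arbitrary units on [0, 65535],
stored as 16-bit when written to TIFF.

**Time-lapses** warp a chosen channel backward through a user-supplied
velocity field (`frame[t+1](x) = frame[t](x − v(x))`, bilinear; exact for
uniform fields) and record the truth on the same grid the flow stage
measures on. Displacements above half the KLT window trigger a warning
because they break the flow algorithm's validity assumption.

**Cell tables** draw UFC / mito% / TRC from truncated normals (defaults
4000 ± 1200 genes, 8 ± 5 %, 80,000 ± 40,000 counts — a plausible filtered
droplet run whose tails straddle the printed thresholds) and per-gene,
per-cluster normalized expression from clipped normals, so gating and
filtering truth are known by construction.

**Embedding pairs** place reference cells around per-cluster centroids in
D = 50 dimensions (centroid entries N(0, 1.3), spread 1, 4 clusters,
150 query / 300 reference cells per cluster by default). Query cells share
the centroid at `mixing = 1`; as mixing decreases the query centroid moves
toward the midpoint between its own and the next cluster's centroid, so
both the labelling agreement (neighbourhood purity) and the unique-mapping
fraction (local crowding) degrade smoothly. The default geometry was chosen
so neither statistic is saturated at the ceiling (clusters overlap softly,
as PC-space cell types do) — with far-separated centroids the agreement
score pins at exactly 1 and carries no information.

All generators derive every random draw from one integer seed
(`numpy.random.default_rng`), making outputs bit-reproducible.

## Segmentation

Images are downsampled ×2 by local averaging before feature extraction;
masks are block-upsampled back at the end. The feature bank is 350 features
per pixel: raw intensity, Gaussian blurs, consecutive-scale differences of
Gaussians, gradient magnitudes and Laplacians over σ ∈ {1, 2.5, 5, 7.5,
10} px, plus DAISY descriptors (radius 15, 4 rings, 8 histograms, 10
orientations = 330 components) computed on a reflect-padded image so every
pixel has a descriptor.

Training converts binary annotations to three classes: the edge class is a
band of `edge_band_px` (default 3, downsampled scale) on both sides of the
mask boundary, inside is the mask minus the band, background the rest. Up
to 8000 pixels per training image are subsampled (seeded, class-
proportional), features are standardized, and a multinomial logistic
regression (lbfgs, C = 1, balanced class weights) is fitted. Classification
is the per-pixel argmax with ties resolved to the lowest class index in the
fixed order background < inside < edge; probability maps sum to 1 by
construction.

Two candidate masks are derived. The *classifier mask* is the region where
P(inside) > P(background) — an edge-neutral decision; taking all
non-background labels instead would overshoot the object by the width of
the outer edge band, since the band straddles the boundary symmetrically.
The *watershed mask* floods the edge-probability landscape from two
markers: the largest connected component of P(inside) > 0.8 (restricting to
the largest suppresses spurious background blobs that would otherwise each
seed a basin) and P(background) > 0.8 components touching the frame border
(falling back to the border itself if none qualify).

Selection replaces the original workflow's visual inspection with explicit
checks: a candidate passes if it is a single connected component, has
solidity ≥ 0.7 and area within [0.25×, 4×] of the median candidate area.
The watershed mask is preferred when it passes, the classifier mask is the
fallback, a manual mask always wins, and if everything fails the failure
modes are raised as an error. The final mask is smoothed (binary closing
then opening with a radius-2 disk, hole filling, largest component) and
upsampled. On the bundled benchmark (train on 3 annotated synthetic images,
evaluate 20 held-out ones at default noise) the pipeline reaches mean
IoU ≈ 0.94 with the watershed mask selected in all cases.

## Morphometrics

**Midline.** The mask skeleton approximates the ridge of the interior
distance transform. Endpoint branches shorter than 1.5 × the local width at
their junction are pruned (these are spurs toward corners); the longest
remaining end-to-end path (double Dijkstra over the 8-connected skeleton
graph) is smoothed with a cubic smoothing spline (s = 2 per point),
resampled at 1 px arc steps, and extended along the end tangents to the
mask boundary. Local width is twice the distance-transform value at each
vertex. A 200 × 40 rectangle yields length 199 ± 1 and width 40.0 — the
end extension recovers the half-width the skeleton cannot reach.

**Degenerate axes.** When the midline is shorter than 1.5 × the mean width
(near-spherical aggregates, e.g. early timepoints) the sample is flagged
`degenerate_axis` and still processed: the axis placement is then
arbitrary, mirroring the known caveat of midline-based AP measurements on
round aggregates, and downstream consumers can filter on the flag.

**Straightening and eccentricity.** The mask (or image) is resampled on an
(arc position × normal offset) grid — bilinear, offsets out to half the
maximum width plus 2 px, frame-clipped with a warning. Eccentricity is
`sqrt(1 − (b/a)²)` from the second moments of the straightened mask (the
only formula consistent with defining a and b as the axes of the
second-moment-equivalent ellipse). Curvature distorts the normal-fan
Jacobian to first order antisymmetrically in the offset, so area is
conserved to well under the 5 % tolerance at realistic bends.

**AP profiles.** At each midline vertex the channel is averaged over the
normal segment restricted to the mask, with *nearest-pixel* sampling: at
the poles bilinear interpolation would blend background intensity across
the boundary and bias the end values. Orientation compares the
reference-channel (T) mass of the two halves and flips so the heavier half
is posterior; an exact tie keeps the original direction and flags it. Arc
positions are rescaled to [0, 1] on a common grid (default 100 points — the
resampling density is a free choice; profiles are smooth at this scale).
Intensity normalization divides by the channel maximum over all profiles
(`global`), within each group (`per_group`), or per profile
(`per_channel_max`, the HCR convention — every channel then peaks at
exactly 1). Replicate bands use the sample (n−1) standard deviation.

**Kymographs** lock the flip decision to the final frame of each movie —
where polarization is strongest — and apply it to all frames, preventing
artifactual axis reversals between rows; failed frames become NaN rows
rather than being interpolated. Replicate kymographs are averaged
pointwise, ignoring missing rows.

**Multichannel (HCR) profiles** compute mask, midline and orientation once
from the T channel and sample every other channel along that same axis,
each normalized to its own maximum.

All coordinates are 0-based (row, col) pixel centers.

## Optical flow

**Registration.** Each frame is aligned to the first by a rigid transform:
a coarse angular search (±10° in 0.25° steps; each candidate is derotated,
translation-registered by subpixel phase correlation, and scored by
residual MSE in the central crop) followed by the winning translation.
Recovery on known transforms is ≤ 0.15° and ≤ 0.1 px. Blank frames get the
identity and a warning.

**KLT.** Flow is measured on a regular grid (every 10 px, inset by half a
window) through a 3-level Gaussian pyramid, coarse to fine. At each level
and point the windowed (20 px) least-squares flow equations are iterated
(≤ 10 iterations, 0.01 px convergence) using template gradients; the
update solves `G δ = −Σ It·∇I` with G the structure tensor. A point is
invalid when the smallest eigenvalue of G falls below 10⁻³ × its trace
(textureless window) — invalid points are NaN, never zero. The pyramid is
what makes 15 px displacements recoverable with a 20 px window; a
single-level run fails the same fixture, which the suite checks.

**Temporal averaging** takes the mean over 16-frame sliding windows
emitted every 4 frames (floor((N−16)/4)+1 windows); a grid point is valid
in a window when valid in at least half its frames. Averaging is linear,
and shorter sequences produce one truncated-window average with a warning.

## Single-cell statistics

QC presets encode the six printed per-dataset threshold sets verbatim with
strict inequalities throughout (a UFC of exactly 2500 fails `UFC > 2500`).
Log-normalization is `ln(1 + scale · count / cell_total)` with scale 10⁴ —
the ecosystem default behind "normalized expression" — and gating
trichotomizes on `> pos` / `≤ neg` cutoffs (T: 1.5 / 0.05, Sox2: 1.0 /
0.05), leaving the in-between cells excluded.

Label transfer assigns each query cell the label of its Euclidean-nearest
reference cell in the shared embedding; exact distance ties resolve to the
lowest reference index for determinism. The transfer-QC statistics per
query cluster are (1) the mean over member cells of the mean distance to
their k = 30 nearest reference cells, (2) the mean fraction of those k
whose label equals the cell's assigned label, and (3) the number of unique
assigned reference cells divided by the cluster size. Per-cell values are
exported alongside the cluster means. Cluster correlation averages the
embedding components within each cluster and takes the Pearson r between
average vectors for every pair; a zero-variance average vector makes r
undefined — such clusters are flagged and their entries set to NaN rather
than propagated silently. Differential expression between two clusters is
the difference of cluster-mean normalized expression per gene, kept when
|difference| ≥ 1 (inclusive — the boundary convention is declared here and
tested) and truncated to the 10 largest per direction.

A practical note observed on the synthetic fixtures: in 50 dimensions the
nearest-neighbour map concentrates on hub cells, so the unique-mapping
fraction of even perfectly mixed clusters saturates near 0.6–0.8 unless
the reference is much denser than the query; the statistic is most
informative as a relative, not absolute, measure.

## What the tests do and do not show

All benchmarks run on the generator, so they demonstrate correctness of
the *computations* — closed-form shape measures, exact recovery of known
gradients, fields and correspondences, brute-force parity of the
neighbour statistics, monotone response to the mixing parameter — under a
noise model chosen for plausibility, not calibrated to any instrument.
Real brightfield variability (illumination gradients, debris, touching
aggregates, focus drift) is not emulated; the classifier's absolute IoU on
real plates will depend on annotation quality, and the mask-selection
thresholds (solidity, area range) are configurable for that reason. The
flow stage assumes mostly in-plane motion of a textured reporter signal;
out-of-plane flows in a real light-sheet volume violate this. Problem
sizes in the test suite and acceptance script (360–420 px frames, 20-image
benchmarks, 3-seed sweeps) were chosen as the smallest sizes at which the
statistics are stable.

## Limitations

No multi-object resolution (one aggregate per frame), no 3D morphometrics
or flow, no clustering/integration/UMAP/pseudotime — those stages of the
source workflow use published tools and are out of scope. The synthetic
noise and illumination model is a declared stand-in; parameters of the
feature bank and DAISY geometry are configurable because the ~350-feature
composition is a reasoned reconstruction rather than a published recipe.
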