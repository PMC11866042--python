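# Methods notes

This note documents the models, defaults and numerical choices behind
`hecif`, and what the synthetic phantoms do and do not establish.

## The scoring model

Fibrosis severity is treated as a continuum. The model never regresses
absolute labels; it is trained purely on *order*: for tiles i, j with
teacher labels y_i − y_j ≥ δ (default δ = 0.1), the network output s(·) is
pushed towards s_i > s_j via the pairwise logistic loss
log(1 + exp(−(s_i − s_j))) (RankNet form; a margin hinge
max(0, m − (s_i − s_j)) is available via `loss="hinge"`). This makes the
model robust to monotone distortions of the teacher scale, which is the
property that lets an H&E model be supervised by a reticulin-based scorer.

* **Backbone** — k conv(3×3)+ReLU+maxpool(2) blocks (default channels
  8/16/32) → global average pool → linear scalar. Deliberately small: the
  test surface is synthetic texture at 64 px, and the architecture is a
  config field, not a contribution. The network and Adam optimiser are
  implemented directly in NumPy (im2col convolutions, manual backprop);
  training is exactly reproducible for a fixed seed because no threaded
  nondeterminism exists in this stack.
* **Calibration** — raw scalar outputs are mapped to CIF ∈ [0, 1] by
  min–max over the *training* outputs, clipped. The slide score is the
  arithmetic mean of its analysable tiles' CIF.
* **Pairwise prediction accuracy** — the fraction of δ-separated ordered
  validation pairs ranked concordantly. Tied predictions receive half
  credit (the AUC convention) so an uninformative constant model scores
  0.5, which keeps the label-shuffled null control centred where it
  belongs; a strict-inequality count would send a degenerate model to 0
  instead.
* **Pair sampling** — training pairs are drawn uniformly with replacement
  from the qualifying set (default 4 pairs per tile); exhaustive
  enumeration is available for oracle checks.

## Phantoms: the stated world

Phantoms exist so that every downstream stage has a checkable ground
truth. Each phantom carries a latent field f(x) ∈ [0, 1] (constant, or
Gaussian-smoothed noise with a stated correlation length), tissue/bone/fat
compartments, and two renderings related by a known affine transform.

* **Fibre strokes** — random-walk polylines (step 1.2 px, heading sd
  0.35 rad, default 36 steps, 3000 candidates per tissue megapixel).
  Candidate k survives iff u_k < f(start_k) with u_k ~ U[0, 1) drawn from
  the same stream regardless of f; pointwise-larger fields therefore keep
  strict supersets of strokes, which *guarantees* (not merely encourages)
  monotone texture density. Stroke geometry is a free modelling choice —
  nothing about real reticulin fibre morphology is claimed.
* **Misalignment** — rotation/isotropic scale about the canvas centre plus
  a translation; the reticulin frame samples the H&E scene through exactly
  this transform, and fresh stroke instances are drawn in the reticulin
  frame (two stains of one section share structure, not pixel noise).
* **Bone loss** — the reticulin-frame bone mask is eroded from its
  boundary (distance-transform ranked, exact pixel count) to
  (1 − bone_loss_fraction) of its area, emulating bone detachment during
  silver staining.
* **Stain drift** — one additive RGB shift per slide (per-stain sd
  configurable); slide-level granularity because the QC analysis compares
  per-slide dominant colours.
* **Defaults** — canvas 2048² at 0.22 µm/px so a 512 px tile spans
  ≈113 µm; fat fraction 0.08 and 3 bone blobs give a plausible marrow
  composition while keeping most tiles analysable. Desk-scale tests use
  smaller canvases (512–1024 px) and 96–128 px tiles purely for speed;
  all geometry scales linearly.

What phantoms do **not** emulate: nuclei, megakaryocytes and other
cytology; scanner optics and compression; deformable (non-affine) warping
between sections; spatially varying stain gradients. A green test
establishes that the algorithms are implemented correctly and behave as
specified on controllable inputs — not that the trained model transfers to
clinical H&E images.

## Registration

Only the two binary tissue masks are used. Initialisation is closed-form:
centroid translation, principal-axis rotation from second moments (both
180° candidates tried, higher-IoU kept), isotropic scale from the area
ratio. Refinement runs Powell over (rotation, log-scale, translation)
maximising the correlation of Gaussian-blurred (σ = 2) masks on a coarse
grid (≤ 384 px), because binary IoU is piecewise constant and cannot be
locally optimised. The result is rescored at full resolution and never
replaces the initialiser if it scores worse. Registrations with final
IoU < 0.5 (configurable) are flagged failed. Only a single global affine
is in scope; matched tiles are cut by mapping tile *centres* and reading
unresampled destination pixels, so no interpolation touches the training
data.

## Tiling and the analysability rule

The grid is anchored at the image origin, stride = tile size, edge-partial
tiles discarded, 0-based half-open pixel coordinates. Tiles require
tissue fraction ≥ 0.5 (configurable) to be kept at all. A tile is
analysable iff fat < 0.50 **and** bone < 0.01, both strictly — ties are
excluded. Whether the composition filter also gates training tiles is
configurable (`apply_composition_filter_for_training`, default off);
analysable-area analyses always apply it.

## Histogram equalisation

Plain global per-channel equalisation:
v → round(255·(cdf(v) − cdf_min)/(N − cdf_min)); a constant channel maps
to mid-scale 128 by convention. Properties relied on downstream: exact
invariance to unclipped global shifts, monotonicity, idempotence within
one grey level. Statistics are per tile by default; a per-slide variant
(`equalize_channels_joint`) pools the histogram across a slide's tiles.

## QC

* **Dominant colour** — modal bin of tissue pixels in a 16³ RGB cube
  (ties → lowest bin id), returned as the mean colour of that bin's
  pixels; deterministic, unlike k-means.
* **CIELAB** — implemented from the standard sRGB→XYZ(D65/2°)→L\*a\*b\*
  formulas with a high-precision matrix whose rows sum exactly to the
  (0.95047, 1, 1.08883) white point, so white maps to (100, 0, 0)
  identically and the scalar formula oracle agrees to 1e−6. (Library
  converters use a rounded matrix that misses that tolerance.)
* **Dispersion comparison** — trace of the per-arm L\*a\*b\* covariance,
  compared by a seeded bootstrap (one-sided, default 2000 resamples).
  Paired per-slide quantities (bone area, tile counts) use the exact
  Wilcoxon signed-rank test. Both are stated substitutes: the analyses
  they mirror do not name their tests.
* **Bone area** — pixel count × (mpp/1000)²; exactly quadratic in mpp.

## Subsampling / heterogeneity

A subsampled region at fraction p is the k = round(p·N) analysable tiles
nearest a uniformly drawn centre tile (Euclidean distance between tile
centres, ties by tile index). Nearest-tile growth realises "expand around
a centre to a target area ratio" deterministically given the centre;
contiguity across tissue gaps is not enforced, and area is counted in
analysable tiles because that is the support of the CIF map. Default
fractions 2/15 … 10/15, 20 draws per fraction (the draw count per
experiment set is otherwise unstated). A slide is heterogeneous iff any
smallest-fraction draw deviates from the whole-slide CIF by strictly more
than 0.1. Max deviations below 1e−12 are snapped to exactly 0 so uniform
maps and fraction-1 draws report a clean zero despite floating-point
summation order.

## Pipeline conventions

Tiles are extracted in the reticulin frame (where the teacher operates)
and matched H&E tiles are cut through the estimated transform; training
uses the first ⌈train_fraction·n⌉ manifest samples in manifest order
(deterministic), scoring/QC/subsampling run on all samples. Every run
writes a provenance record (config hash, seeds, package version, training
curve CRC, artefact index). All randomness flows from explicit integer
seeds; two runs with identical manifest/config/seed produce byte-identical
score tables.

## Known limitations

* The ranking model is desk-scale; 512 px native-resolution training works
  through the same code path but is slow on one CPU.
* Registration assumes a dominant, roughly rigid tissue profile; masks
  with strong symmetry or heavy clipping can defeat the principal-axis
  initialisation (the IoU floor flags such cases).
* The phantom teacher reads the latent field directly; no attempt is made
  to model teacher noise beyond the frame mismatch between stains.
* Heterogeneity classification inherits the sampling variance of its
  draws: with few draws a genuinely heterogeneous slide can be missed;
  the draw count is configurable.
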