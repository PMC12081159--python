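# Methods

This note documents the models implemented in `histopatch`, the
parameters that matter, the numerical choices, and what the synthetic
test bed does and does not establish.

## Reliability detection and initialization

The filtering scheme is written in the guided-filter idiom: a color
guidance raster `I` (normalized to [0, 1]) paired with a scalar working
channel `D` on the same grid. On plain RGB histology input, `D` is Rec.
601 luminance — the scheme's structure comes from guided depth
upsampling, and a scalar working channel preserves it on photometric
images.

A pixel is *unreliable* when max−min of `D` over the (2r+1)² reference
window exceeds τ. Defaults: `window_radius = 1` (the smallest symmetric
window) and `τ = 0.1` on the [0, 1] scale; both are configurable since
no principled value exists — τ trades repair coverage against trusting
genuine edges. Windows are clipped at image borders; no padded values
are invented (replicate-padding in the extrema filters is exact for
clipped windows because clamped indices duplicate in-window samples).

Upsampling in the restoration path uses corner-aligned separable
interpolation: bilinear for the working channel that feeds the filter
(it does not overshoot at edges), cubic spline optionally for a
prototype map. Corner alignment makes output sample `i` interpolate at
input coordinate `i·(n−1)/(N−1)`, which is reproducible by a hand
oracle.

A first-order refinement then rescues fine detail: pixels where the
central-difference derivative of `D` changes sign across them along
either axis (one-pixel ridges/valleys — the derivative's zero crossing
sits on the feature) are restored to reliable. Refinement is monotone:
it never demotes a reliable pixel.

## Propagation order and the two-direction confidence field

`T` is the chessboard (8-neighbor) distance transform to the reliable
set; wave `t` of the filter processes exactly the level set `T = t`,
which guarantees every pixel has at least one already-processed neighbor
at its turn (asserted). The propagation direction `∇T` is the unit
central-difference gradient of `T`; where it vanishes, the field falls
back to the direction of increasing distance (away from the nearest
reliable pixel, computed with a deterministic Euclidean
distance-transform index map), and on a fully reliable image to an
arbitrary unit vector that is never consumed.

Each pixel stores confidence toward `+∇T` and `−∇T`. Reliable pixels
carry [1, 0]: full trust flowing outward into the unreliable region,
none backward; since propagation only ever consumes values from lower
`T`, the backward slot of a source is never on a propagation path, and
reliable neighbors always contribute their `+` slot. Unreliable
neighbors contribute the slot best aligned (sign of the dot product,
ties to `+`) with the direction being served.

The decay is **per hop**: the prefactor on a neighbor's confidence is
`a^(T(x)−T(y))`, which is `a` under the chessboard ordering, so the
accumulated decay at distance `T` is exactly `a^T(x)`. This choice is
forced by the scheme's own reduction: with `γ_I = γ_D = 0` and `δ = 1`
all consistency weights collapse to 1 and the confidence must equal
`a^T(x)` (a literal `a^T(x)` prefactor per step would instead compound
to `a^(T(T+1)/2)`). The reduction is verified against an independently
written distance-decay filter (own breadth-first distance transform,
plain loops) to 1e−10 on random masked rasters.

Defaults `a = 0.8`, `γ_I = (0.1)⁻² = 100`, `γ_D = (0.01)⁻² = 10⁴`,
`δ = 0`. The γ values are read as inverse squared bandwidths of the
photometric kernels; both remain configurable because the exponent
notation admits another reading.

Numerical guards: weight denominators below the smallest normal double
are treated as zero (products of two Gaussian kernels underflow to
denormals on strong edges, where division is meaningless); a pixel whose
weights all vanish (possible with `δ = 0` at orthogonal normals)
receives the plain mean of its processed neighbors so that every
unreliable pixel is assigned exactly once. Filtered values are convex
combinations of processed values, hence always inside the hull of the
reliable values.

## Correlogram descriptors

Colors are quantized to `m` colors — uniform per-channel binning when
`m` is a perfect cube (default `m = 64`, i.e. 4×4×4 RGB bins), seeded
k-means otherwise. The correlogram `γ[i, j, k]` is the probability that
an ordered pair at exact L∞ distance `k` pairs color `c_i` with `c_j`,
computed by shifted-array counting over the 8k offsets of the
distance-`k` square ring. Pairs leaving the image are excluded from
numerator **and** denominator, so borders do not bias the
probabilities; rows of absent colors (or empty rings) are zero, and
`Σ_j γ[i, j, k] = 1` otherwise. The default distance set {1, 3, 5, 7}
spans sub-gland to gland scale at 32–64 px tiles; larger `d` costs
O(m²d) space and adds little at this resolution. The autocorrelogram is
the diagonal slice (`O(md)` storage). An O(n⁴) all-pairs enumeration,
kept deliberately naive, is the equality oracle in the tests.

## Nonlocal patch manifold and spectral filtering

Every pixel contributes its `s × s` patch (reflect padding, `s = 5` by
default; printed formulas compare patch pairs `i, j`). The Gaussian
kernel with bandwidth σ — default: median pairwise patch distance over a
seeded 1000-pair sample, floored to 1 for constant rasters — produces a
dense, connected graph; `L = D − W` is symmetric PSD with the constant
vector in its kernel. Kernels are quadratic in node count, so graphs
larger than `sample_cap` (2048 standalone, 256 inside tile features) are
built on a seeded uniform subsample of centers; low-order spectral
statistics are stable under this. Eigenvectors are sign-fixed (first
non-negligible entry positive) for reproducibility; exact symmetry of
`W` is enforced by symmetrization before decomposition.

Spectral filtering projects the per-node intensity signal onto the first
`k` eigenvectors, scales the coefficients by per-band gains, and adds
back the unprojected residual — unit gains reproduce the input exactly.
The classifier consumes the normalized squared coefficients on the first
`k_bands = 8` eigenvectors; band 0 carries the mean (so the spectrum
above band 0 is offset-invariant), and an identically zero signal is
assigned all-band-0 energy by convention.

## Memory-cell tile classifier

Tile features = flattened autocorrelogram (m·|d| = 256 values) ‖
low-band graph energies (8 values), min–max normalized per feature with
training-set statistics and clipped to [0, 1]; affinity is Euclidean
distance divided by √dim, hence in [0, 1]. The placement threshold is
the mean pairwise affinity over the training features.

Training presents examples in a seeded shuffled order. A candidate
farther than the threshold from every same-label cell founds a new cell;
otherwise its nearest same-label cell (lowest index on ties) gains one
stimulation and moves toward the candidate by 1/stimulation — a running
mean of everything the cell absorbed, which realizes prototype "area
growth". At capacity (default 32) the least-stimulated cell is replaced,
with one guard this package adds: a class's last cell is never evicted,
since scoring needs at least one prototype per class. Queries take the
nearest cell's label; the malignancy score is
`d_benign/(d_benign + d_malignant)` over nearest-cell distances, 0.5
when equidistant, extreme when the query coincides with a prototype.

Heatmaps paint per-tile scores into image coordinates (overlaps
averaged). They are a functional stand-in for activation mapping on a
trained network — a localization readout from the tile classifier, not a
claim of equivalence to gradient-based saliency.

Evaluation: confusion-based accuracy/precision/recall/F1 (malignant
positive) and AUC by the midrank Mann–Whitney statistic; tests verify it
against trapezoidal integration of the ROC curve (scikit-learn) to
1e−10 including ties. The stratified 70/30 split apportions per-class
training counts by largest remainder, so a 10-item balanced set splits
7/3 exactly.

## Synthetic test bed

The generator emulates the two morphological regimes the classifier must
separate. A gland is a perturbed annulus: epithelium ring around a lumen
at 0.45 of the boundary radius, boundary radius modulated by harmonics
2–5 with amplitude (1 − regularity); centers sit on an even grid with
jitter and radius growth scaled by (1 − regularity), so benign tissue
(regularity 0.9) shows separated regular rings and malignant tissue
(regularity 0.2) crowded, fused, ragged masses. Colors come from a
three-entry stain-like palette (stroma pink, epithelium purple, lumen
off-white); corruption is additive Gaussian noise (σ = 4 gray levels by
default) clipped to [0, 255]. Per-image seeds are master + index.

Default study conditions: 200 images per class at 64 px, one tile per
image, degrade-restore enabled (factor 2, noise σ = 5), 70/30 stratified
split, master seed 42. Under these conditions the pipeline reaches test
accuracy ≥ 0.99 and AUC ≈ 1.0; insert-localization fixtures (96 px
benign background, 48 px malignant insert, matched gland density) are
localized in ≥ 95% of cases. Problem sizes (16×16 rasters for filter
oracles, ≤ 200-node graphs, 8×8 images for the exact correlogram oracle)
were chosen so every oracle is exhaustively checkable; they are small by
design, not by approximation.

What passing does **not** show: the palette has no stain variation,
glands have no nuclear detail, noise is i.i.d. Gaussian rather than
scanner-structured, and class difference is governed by a single
morphology knob. Results on this bed demonstrate correctness of the
implementation and internal consistency of the method, not clinical
performance on real prostate histopathology.

## Known limitations

- The ordered filter is O(waves × pixels) with dense per-wave vector
  work; no pyramid or multi-scale variant is provided.
- Patch-graph eigendecomposition is dense (O(n³) in node count); no
  Nyström extension.
- The memory-cell scheme has no per-cell forgetting or affinity-based
  resource competition beyond least-stimulated replacement.
- Non-square images are supported everywhere except the synthetic
  generator, which renders square fields.
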