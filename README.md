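# histopatch

A toolkit for prostate-histopathology image analysis built from three
cooperating pieces:

1. **Reliability-guided confidence-propagation filtering.** Pixels whose
   local max–min spread exceeds a threshold τ are marked unreliable and
   repaired in geodesic order — the chessboard distance transform *T* to
   the reliable set fixes the processing waves, so pixels repaired early
   feed the repair of later ones. Each pixel carries a two-direction
   confidence pair C̄(x) = [C(x; +∇T), C(x; −∇T)] propagated with per-hop
   decay *a* and two pairwise consistency weights,

   B(x,y) = exp(−γ_I‖I_x−I_y‖²)·exp(−γ_D(D_x−D_y)²),
   G(x,y) = max(cos∠(∇x, ∇y), δ),

   and the ordered filter replaces each unreliable pixel with the
   B·G·C-weighted mean of its already-processed neighbors. Reliable
   pixels pass through bit-identically.

2. **Texture descriptors.** The color correlogram
   γ<sub>c_i,c_j</sub><sup>(k)</sup> — the probability that a pixel at
   exact L∞ distance *k* from a color-c_i pixel has color c_j — and its
   diagonal, the autocorrelogram, capture spatial color coherence. The
   nonlocal patch manifold {R_i f} with Gaussian kernel
   W[i,j] = exp(−‖R_i f − R_j f‖²/2σ²) yields a graph Laplacian
   L = D − W whose eigenbasis U gives data-adaptive "graph frequencies":
   band-wise gains adjust contrast in manifold space, and normalized
   low-band energies serve as texture features.

3. **Memory-cell tile classification.** Tiles are classified by an
   immune-inspired nearest-prototype scheme: training features farther
   than the mean pairwise affinity of the training set from every
   same-label prototype found new memory cells; others stimulate and shift their
   nearest cell by a running mean. The malignancy score
   d_benign/(d_benign+d_malignant) drives ROC/AUC evaluation and per-tile
   score heatmaps that localize malignant regions.

A seeded synthetic-tissue generator (regular ring glands for benign,
jittered fused blobs for malignant, stain-like palette, Gaussian noise)
makes every stage testable end to end without clinical data.

Intended users: image-analysis researchers who want a transparent,
dependency-light reference implementation of these primitives with exact
oracles and property tests, not a clinical-grade classifier.

## Worked example

```sh
python examples/05_classify_and_heatmap.py
```

prints (40 images per class, 32-px tiles, seed 7):

```
memory cells: 3 (threshold 0.109)
test accuracy 1.000, AUC 1.000, confusion {'tp': 12, 'tn': 12, 'fp': 0, 'fn': 0}
heatmap mean inside insert 0.573 vs background 0.552
```

The classifier separates the held-out tiles perfectly at this scale, and
on an image with a known malignant insert the per-tile score is higher
inside the insert than over the benign background — tile-level
localization without pixel supervision. The other examples demonstrate
the generator (`01`), restoration (`02` — luminance RMSE drops from
0.0767 to 0.0699 after repairing 26% unreliable pixels), correlogram
signatures (`03`), and spectral contrast adjustment (`04`).

A thin CLI wraps the same calls:

```sh
histopatch --seed 42 --out out/ simulate --n-per-class 5
histopatch --out out/ filter out/benign_0000.png
histopatch --seed 42 --out out/ run
```

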