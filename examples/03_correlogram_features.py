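"""Color correlogram and autocorrelogram of a tissue image.

The autocorrelogram tracks how often each quantized color co-occurs with
itself at chessboard distance k — a compact spatial-coherence signature
that separates orderly benign texture from fused malignant texture.
"""

import numpy as np

from histopatch import TissueSpec, correlogram, generate_tissue_image, quantize_colors

for reg, name in [(0.9, "benign"), (0.2, "malignant")]:
    img = generate_tissue_image(TissueSpec(seed=5, regularity=reg))
    q = quantize_colors(img, m=64)  # 4x4x4 uniform RGB bins
    table = correlogram(q, d_set=(1, 3, 5, 7))
    ac = table.ac
    top = np.argsort(table.h)[-3:][::-1]
    print(f"{name}: {np.count_nonzero(table.h)} of 64 colors occupied")
    for c in top:
        print(f"  color {c:2d} (n={table.h[c]:5d})  ac(k=1..7) = "
              + " ".join(f"{ac[c, i]:.3f}" for i in range(4)))
# Higher ac at small k = color patches are spatially coherent; the decay
# with k reflects the gland scale. Malignant images keep self-correlation
# high at larger k because fused epithelial masses are bigger.
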