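"""Degrade an image and repair it with confidence-propagation filtering.

The restoration path: block-downsample + noise, bilinear upsampling,
max-min reliability detection with first-order edge refinement, chessboard
propagation ordering, two-direction confidence, and the ordered filter.
"""

import numpy as np

from histopatch import (
    GuidedImage,
    PropagationParams,
    TissueSpec,
    compute_order_field,
    degrade_image,
    detect_unreliable,
    generate_tissue_image,
    init_upsample,
    ordered_filter,
    propagate_confidence,
    refine_with_edge_filter,
)

img = generate_tissue_image(TissueSpec(seed=3))
low = degrade_image(img, factor=2, noise_sd=5.0, seed=0)
up = np.clip(init_upsample(low.astype(float) / 255.0, 2, "bilinear"), 0, 1)
guided = GuidedImage.from_rgb(up)

mask = refine_with_edge_filter(detect_unreliable(guided.D, 1, 0.1), guided.D)
order = compute_order_field(mask)
conf = propagate_confidence(order, guided, PropagationParams())
restored = ordered_filter(guided, order, conf)

truth = GuidedImage.from_rgb(img).D
rmse_before = np.sqrt(((guided.D - truth) ** 2).mean())
rmse_after = np.sqrt(((restored - truth) ** 2).mean())
print(f"unreliable pixels: {(~mask.mask).sum()} of {mask.mask.size} "
      f"({(~mask.mask).mean():.0%}), repaired in {order.n_steps} waves")
print(f"luminance RMSE vs clean original: {rmse_before:.4f} -> {rmse_after:.4f}")
# The filter only rewrites unreliable pixels; reliable ones pass through
# bit-identically, so any RMSE change comes from the repaired region.
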