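"""Calibrate a 9-hue greenness palette and measure hue abundance.

Rosettes are painted from a known 9-colour green palette; pooling their
pixels and clustering with k-means (k=9, Euclidean RGB) should rebuild the
palette, and every plant's area-normalised hue profile should match the
renderer's exact composition.
"""

import numpy as np

from phenorosette.color import (
    build_hue_palette,
    collect_calibration_pixels,
    hue_abundance,
    segment_colors,
)
from phenorosette.rgb import TrayLayout, clean_mask, crop_tray, segment_rosette
from phenorosette.synthetic import (
    DEFAULT_LEAF_PALETTE,
    Treatment,
    TrayStyle,
    assign_growth_truth,
    generate_design,
    render_tray_image,
)

design = generate_design(["Col-0", "C24"], [Treatment("control", 0), Treatment("salt", 100)],
                         5, range(8), seed=1)
gt = assign_growth_truth(design, area0=800, gr_control=150, seed=2)
style = TrayStyle(soil_noise_sd=0.0)
image, truths = render_tray_image(design, 0, 4, growth_truth=gt, style=style, seed=3,
                                  image_size=(640, 480))

layout = TrayLayout()
pots = crop_tray(image, layout)
pairs, order = [], []
for p in design.tray_plants(0).itertuples():
    crop = pots[p.row * layout.cols + p.col]
    veg = segment_rosette(crop).mask & clean_mask(segment_rosette(crop)).mask
    pairs.append((crop, veg))
    order.append((p.plant_id, crop, veg))

palette = build_hue_palette(collect_calibration_pixels(pairs, seed=0), k=9, seed=0)
dist = np.linalg.norm(palette.centroids - DEFAULT_LEAF_PALETTE.astype(float), axis=1)
print("rebuilt palette (dark -> light) vs generating colours:")
for i, (c, d) in enumerate(zip(palette.centroids, dist), start=1):
    print(f"  hue {i}: RGB=({c[0]:5.1f},{c[1]:5.1f},{c[2]:5.1f})  distance to truth={d:.2g}")

pid, crop, veg = order[0]
ab = hue_abundance(segment_colors(crop, veg, palette), int(veg.sum()), plant_id=pid, k=9)
print(f"\nhue abundance of {pid} (fractions of rosette area, sum={ab.fractions.sum():.3f}):")
print("  " + " ".join(f"{f:.3f}" for f in ab.fractions))

# With noise-free rendering the k-means centroids coincide with the painting
# palette (distance ~0) and the abundance vector is an exact probability
# vector over the nine hues.
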