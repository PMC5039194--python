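"""Render a synthetic tray and segment the rosettes back out.

Builds a 12-plant experiment (2 accessions x control/salt x 3 replicates),
renders one 640x480 tray image for day 5, then runs the segmentation stage
(crop -> excess-green threshold -> mask cleaning) and compares each
recovered rosette area with the renderer's exact ground truth.
"""

from phenorosette.rgb import TrayLayout, clean_mask, crop_tray, segment_rosette
from phenorosette.synthetic import (
    Treatment,
    assign_growth_truth,
    generate_design,
    render_tray_image,
)

design = generate_design(
    ["Col-0", "C24"], [Treatment("control", 0), Treatment("salt", 100)],
    n_replicates=3, days=range(8), seed=1,
)
truth_params = assign_growth_truth(design, area0=500, gr_control=150, seed=2)
image, truths = render_tray_image(
    design, tray_index=0, day=5, growth_truth=truth_params, seed=3, image_size=(640, 480)
)

layout = TrayLayout(rows=4, cols=5)
pots = crop_tray(image, layout)
print(f"{'plant':<22}{'treatment':<10}{'true px':>9}{'segmented px':>14}{'error %':>9}")
for p in design.tray_plants(0).itertuples():
    mask = clean_mask(segment_rosette(pots[p.row * layout.cols + p.col]))
    true_area = truths[p.plant_id].area_px
    err = 100 * abs(mask.area_px - true_area) / true_area
    print(f"{p.plant_id:<22}{p.treatment:<10}{true_area:>9}{mask.area_px:>14}{err:>9.2f}")

# Salt-treated plants are smaller (their growth model runs at 60% of the
# control rate by day 5); segmentation recovers every area within a few %.
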