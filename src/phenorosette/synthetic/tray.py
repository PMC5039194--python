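"""Synthetic top-view tray renderer with exact per-pot ground truth.

Rosettes are drawn as fans of rotated ellipses ("leaves") centred in their
pot cells.  Each leaf is painted in one colour from a small green palette,
so the rendered image carries a known hue composition; the union of leaf
ellipses is the exact ground-truth mask.  The renderer is not meant to be
photorealistic — it exists to give every downstream stage (segmentation,
morphometrics, colour clustering) a pixel-exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .growth import INTERVALS_PROTOCOL, area_at

#: nine green hues, dark to light (luminance-increasing), used as the default
#: leaf palette; mirrors a 9-cluster greenness scale.
DEFAULT_LEAF_PALETTE = np.array(
    [
        (20, 70, 25),
        (30, 90, 30),
        (42, 105, 36),
        (54, 120, 42),
        (66, 135, 50),
        (80, 150, 60),
        (96, 165, 72),
        (116, 180, 88),
        (140, 196, 108),
    ],
    dtype=np.uint8,
)

#: full native resolution of the top-view camera (width, height)
NATIVE_IMAGE_SIZE = (2560, 1920)


@dataclass
class TrayStyle:
    """Rendering knobs: soil appearance, leaf geometry and colouring."""

    soil_rgb: tuple[int, int, int] = (120, 92, 60)
    soil_noise_sd: float = 4.0
    leaf_palette: np.ndarray = field(default_factory=lambda: DEFAULT_LEAF_PALETTE.copy())
    hue_weights: np.ndarray | None = None  # uniform if None
    leaf_jitter_sd: float = 0.0
    n_leaves_range: tuple[int, int] = (6, 12)
    leaf_aspect: float = 2.6
    angle_jitter_sd: float = 0.18  # radians
    max_fill: float = 0.4  # rosette area cap as a fraction of the pot cell

    def weights(self) -> np.ndarray:
        k = len(self.leaf_palette)
        w = np.full(k, 1.0 / k) if self.hue_weights is None else np.asarray(self.hue_weights, float)
        if len(w) != k or np.any(w < 0):
            raise ValueError("hue_weights must be non-negative, one per palette colour")
        return w / w.sum()


@dataclass
class PotTruth:
    """Exact ground truth for one rendered pot."""

    plant_id: str
    day: int
    row: int
    col: int
    mask: np.ndarray  # bool, pot-cell sized
    hue_fractions: np.ndarray | None  # length-k, sums to 1; None for empty pots
    area_target: float
    area_px: int


def _leaf_geometry(n_leaves: int, aspect: float, angle_jitter_sd: float, rng) -> list[tuple]:
    """Per-leaf (angle, relative length, relative width) for a rosette fan."""
    base = np.linspace(0.0, 2.0 * np.pi, n_leaves, endpoint=False)
    angles = base + rng.normal(0.0, angle_jitter_sd, n_leaves)
    lengths = rng.uniform(0.75, 1.0, n_leaves)
    widths = lengths / aspect
    return list(zip(angles, lengths, widths))


def _paint_rosette(cell_shape, target_area, style: TrayStyle, rng):
    """Draw one rosette; returns (label image, mask).

    Labels are palette indices, -1 for background.  The linear scale of the
    leaf fan is calibrated iteratively so the painted pixel count lands
    within 10% (usually 5%) of ``target_area``.
    """
    h, w = cell_shape
    labels = np.full(cell_shape, -1, dtype=np.int16)
    if target_area <= 0:
        return labels, np.zeros(cell_shape, bool)
    if target_area > style.max_fill * h * w:
        raise ValueError(
            f"area target {target_area:.0f} px exceeds {style.max_fill:.0%} of the "
            f"{h}x{w} pot cell; plant does not fit"
        )
    n_leaves = int(rng.integers(style.n_leaves_range[0], style.n_leaves_range[1] + 1))
    geom = _leaf_geometry(n_leaves, style.leaf_aspect, style.angle_jitter_sd, rng)
    hue_idx = rng.choice(len(style.leaf_palette), size=n_leaves, p=style.weights())
    order = rng.permutation(n_leaves)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # initial semi-major from the disjoint-leaf area estimate, with ~20% overlap
    a0 = np.sqrt(target_area * style.leaf_aspect / (0.8 * n_leaves * np.pi))

    def render(scale):
        lab = np.full(cell_shape, -1, dtype=np.int16)
        for i in order:
            ang, ln, wd = geom[i]
            a, b = scale * ln, scale * wd
            r0 = cy + a * np.sin(ang)
            c0 = cx + a * np.cos(ang)
            rr, cc = draw_ellipse(r0, c0, b, a, rotation=-ang, shape=cell_shape)
            lab[rr, cc] = hue_idx[i]
        return lab

    scale = a0
    max_scale = 0.48 * min(h, w)  # keep leaves inside the cell
    for _ in range(8):
        labels = render(min(scale, max_scale))
        area = int((labels >= 0).sum())
        if area == 0:
            scale *= 1.5
            continue
        if abs(area - target_area) <= 0.05 * target_area:
            break
        scale = min(scale, max_scale) * np.sqrt(target_area / area)
    mask = labels >= 0
    return labels, mask


def render_tray_image(
    design,
    tray_index: int,
    day: int,
    *,
    growth_truth=None,
    style: TrayStyle | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = NATIVE_IMAGE_SIZE,
    intervals=INTERVALS_PROTOCOL,
    area_targets: dict | None = None,
):
    """Render one tray on one day.

    Per-plant area targets come either from ``area_targets`` (plant_id ->
    px) or from the piecewise-linear growth model via ``growth_truth`` (the
    frame from :func:`assign_growth_truth`).  Returns ``(image, truths)``
    where image is uint8 RGB (height x width x 3) and truths maps plant_id
    to :class:`PotTruth`.
    """
    style = style or TrayStyle()
    width, height = image_size
    rows, cols = design.tray_rows, design.tray_cols
    if width % cols or height % rows:
        raise ValueError(f"image size {image_size} not divisible into {rows}x{cols} cells")
    cell_h, cell_w = height // rows, width // cols

    rng = np.random.default_rng((seed, tray_index, day))
    img = np.empty((height, width, 3), dtype=float)
    img[...] = np.asarray(style.soil_rgb, float)
    if style.soil_noise_sd > 0:
        img += rng.normal(0.0, style.soil_noise_sd, img.shape)

    if area_targets is None:
        if growth_truth is None:
            raise ValueError("provide growth_truth or explicit area_targets")
        gt = growth_truth.set_index("plant_id")
        area_targets = {
            pid: float(
                area_at(day, gt.at[pid, "area0"], gt.at[pid, "gr_early"], gt.at[pid, "gr_late"], intervals)
            )
            for pid in gt.index
        }

    truths: dict[str, PotTruth] = {}
    palette = style.leaf_palette.astype(float)
    for p in design.tray_plants(tray_index).itertuples():
        target = float(area_targets.get(p.plant_id, 0.0))
        labels, mask = _paint_rosette((cell_h, cell_w), target, style, rng)
        y0, x0 = p.row * cell_h, p.col * cell_w
        cell = img[y0 : y0 + cell_h, x0 : x0 + cell_w]
        cell[mask] = palette[labels[mask]]
        if style.leaf_jitter_sd > 0:
            cell[mask] += rng.normal(0.0, style.leaf_jitter_sd, (int(mask.sum()), 3))
        area = int(mask.sum())
        if area:
            counts = np.bincount(labels[mask], minlength=len(palette))
            fracs = counts / area
        else:
            fracs = None
        truths[p.plant_id] = PotTruth(
            plant_id=p.plant_id,
            day=day,
            row=p.row,
            col=p.col,
            mask=mask,
            hue_fractions=fracs,
            area_target=target,
            area_px=area,
        )

    return np.clip(img, 0, 255).astype(np.uint8), truths
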