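"""Tray image -> per-pot crops -> binary rosette masks -> pixel areas.

Background subtraction uses a colour-index threshold: a pixel is vegetation
when its excess-green index 2G − R − B exceeds a threshold *and* its green
channel clears a floor.  This is a transparent, reproducible stand-in for
proprietary platform segmentation; the threshold is a configuration value.
Mask cleaning removes sub-``min_object_px`` speckles, closes small holes and
keeps the largest connected component (ties broken by lowest centroid row,
then column).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

DEFAULT_EXG_THRESHOLD = 30.0
DEFAULT_MIN_GREEN = 40.0


@dataclass(frozen=True)
class TrayLayout:
    """Row-major grid of pot cells tiling the usable image region.

    Coordinates are 0-based with the origin at the top-left; each cell is a
    half-open interval in both axes.  ``margin`` pixels are trimmed from
    every image edge before tiling.
    """

    rows: int = 4
    cols: int = 5
    margin: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"layout must have positive rows/cols, got {self.rows}x{self.cols}")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    def cell_shape(self, image_shape) -> tuple[int, int]:
        h = image_shape[0] - 2 * self.margin
        w = image_shape[1] - 2 * self.margin
        if h <= 0 or w <= 0:
            raise ValueError(f"margin {self.margin} leaves no usable region in {image_shape}")
        if h % self.rows or w % self.cols:
            raise ValueError(
                f"usable region {h}x{w} not divisible into {self.rows} rows x "
                f"{self.cols} cols (expected multiples of {self.rows} and {self.cols})"
            )
        return h // self.rows, w // self.cols


@dataclass
class RosetteMask:
    """Binary plant/background map for one pot crop."""

    mask: np.ndarray
    plant_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentationParams:
    exg_threshold: float = DEFAULT_EXG_THRESHOLD
    min_green: float = DEFAULT_MIN_GREEN
    min_object_px: int = 20
    closing_radius: int = 1


def crop_tray(image: np.ndarray, layout: TrayLayout) -> list[np.ndarray]:
    """Split a tray image into rows*cols pot crops in row-major order.

    The crops partition the usable region exactly: concatenating them
    reconstructs it.  Raises if the region does not divide evenly.
    """
    image = np.asarray(image)
    ch, cw = layout.cell_shape(image.shape[:2])
    m = layout.margin
    crops = []
    for r in range(layout.rows):
        for c in range(layout.cols):
            y0, x0 = m + r * ch, m + c * cw
            crops.append(image[y0 : y0 + ch, x0 : x0 + cw])
    return crops


def segment_rosette(pot_image: np.ndarray, params: SegmentationParams | None = None) -> RosetteMask:
    """Threshold green vegetation in an 8-bit RGB pot crop."""
    params = params or SegmentationParams()
    img = np.asarray(pot_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    rgb = img.astype(float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    exg = 2.0 * g - r - b
    return RosetteMask((exg > params.exg_threshold) & (g > params.min_green))


def clean_mask(
    mask: RosetteMask | np.ndarray,
    min_object_px: int = 20,
    closing_radius: int = 1,
) -> RosetteMask:
    """Speckle removal + hole closing + largest-component selection.

    Idempotent; an empty mask comes back empty.  When several components tie
    for the largest area, the one with the lowest centroid row (then column)
    wins, a deterministic rule for pots touched by a neighbour's leaf.
    """
    rm = mask if isinstance(mask, RosetteMask) else RosetteMask(mask)
    m = rm.mask
    if m.any() and min_object_px > 1:
        # drop connected speckles strictly smaller than min_object_px
        m = morphology.remove_small_objects(m, max_size=min_object_px - 1)
    if m.any() and closing_radius > 0:
        # closing fills holes and concavities up to the structuring radius only
        m = morphology.closing(m, morphology.disk(closing_radius)).astype(bool)
    if m.any():
        labels, n = ndi.label(m)
        if n > 1:
            areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            best = np.flatnonzero(areas == areas.max()) + 1
            if len(best) > 1:
                cents = ndi.center_of_mass(m, labels, index=best)
                best = [lab for _, lab in sorted(zip(cents, best), key=lambda t: (t[0][0], t[0][1]))]
            m = labels == best[0]
    return RosetteMask(m, plant_id=rm.plant_id, day=rm.day)


def rosette_area(mask: RosetteMask | np.ndarray) -> int:
    """Projected rosette area: the count of foreground pixels."""
    rm = mask if isinstance(mask, RosetteMask) else RosetteMask(mask)
    return rm.area_px
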