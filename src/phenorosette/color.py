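"""Greenness analysis: a k-hue palette by k-means and per-plant hue abundance.

A single palette is calibrated per experiment from rosette pixels pooled
across treatments and across the start, middle and end of the phenotyping
period, so hue indices are comparable between plants and days.  Every
rosette pixel is then assigned to its nearest centroid in RGB space and the
per-hue pixel counts are divided by the rosette area, giving an
area-normalised greenness profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

DEFAULT_K = 9


@dataclass
class HuePalette:
    """k base hues (RGB centroids), ordered dark to light by luminance."""

    centroids: np.ndarray  # (k, 3) float, RGB in [0, 255]
    wcss: float  # within-cluster sum of squares of the calibration fit
    seed: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, float)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hue": np.arange(1, self.k + 1),
                "R": self.centroids[:, 0],
                "G": self.centroids[:, 1],
                "B": self.centroids[:, 2],
            }
        )


@dataclass
class HueAbundance:
    """Area-normalised hue fractions for one plant on one day."""

    plant_id: str
    day: int
    fractions: np.ndarray | None  # length-k; None = zero-area plant (missing)

    @property
    def missing(self) -> bool:
        return self.fractions is None


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luma, used only to give hues a stable dark-to-light order."""
    rgb = np.asarray(rgb, float)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def collect_calibration_pixels(
    images_masks,
    *,
    strata=None,
    cap_per_image: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pool mask-true RGB pixels from calibration images.

    ``images_masks`` is a sequence of (image, mask) pairs; ``strata`` an
    optional parallel list of labels (e.g. "start"/"middle"/"end").  With
    ``cap_per_image`` set, each image contributes at most that many pixels,
    sampled without replacement under the seed.  Background-only images
    contribute nothing; an entirely empty pool is an error.
    """
    rng = np.random.default_rng(seed)
    frames = []
    strata = strata if strata is not None else [""] * len(images_masks)
    for (img, mask), stratum in zip(images_masks, strata):
        img = np.asarray(img)
        mask = np.asarray(getattr(mask, "mask", mask), bool)
        px = img[mask].reshape(-1, 3).astype(float)
        if cap_per_image is not None and len(px) > cap_per_image:
            px = px[rng.choice(len(px), cap_per_image, replace=False)]
        if len(px):
            frames.append(pd.DataFrame({"R": px[:, 0], "G": px[:, 1], "B": px[:, 2], "stratum": stratum}))
    if not frames:
        raise ValueError("no rosette pixels found in any calibration image")
    return pd.concat(frames, ignore_index=True)


def build_hue_palette(pixels: pd.DataFrame, k: int = DEFAULT_K, seed: int = 0) -> HuePalette:
    """k-means in RGB space (k-means++, 10 restarts, best WCSS kept)."""
    X = pixels[["R", "G", "B"]].to_numpy(float)
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k:
        raise ValueError(f"need at least k={k} distinct colours, dataset has {n_distinct}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    km.fit(X)
    order = np.argsort(luminance(km.cluster_centers_), kind="stable")
    return HuePalette(centroids=km.cluster_centers_[order], wcss=float(km.inertia_), seed=seed)


def segment_colors(pot_image: np.ndarray, mask, palette: HuePalette) -> np.ndarray:
    """Label every mask-true pixel with its nearest palette hue (0-based).

    Euclidean distance in RGB; ties resolve to the lowest hue index.
    Background pixels get label -1.
    """
    img = np.asarray(pot_image)
    m = np.asarray(getattr(mask, "mask", mask), bool)
    if img.shape[:2] != m.shape:
        raise ValueError(f"image {img.shape[:2]} and mask {m.shape} are not aligned")
    labels = np.full(m.shape, -1, dtype=np.int16)
    px = img[m].reshape(-1, 3).astype(float)
    if len(px):
        d2 = ((px[:, None, :] - palette.centroids[None, :, :]) ** 2).sum(axis=2)
        labels[m] = np.argmin(d2, axis=1)  # argmin takes the first (lowest) on ties
    return labels


def hue_abundance(labels: np.ndarray, rosette_area: int, *, plant_id: str = "", day: int = 0, k: int | None = None) -> HueAbundance:
    """Per-hue pixel counts divided by the rosette area.

    ``rosette_area`` must equal the number of labelled pixels; a zero-area
    plant yields a flagged missing record instead of dividing by zero.
    """
    lab = np.asarray(labels)
    fg = lab[lab >= 0]
    if fg.size != rosette_area:
        raise ValueError(f"area mismatch: {fg.size} labelled pixels vs rosette_area={rosette_area}")
    if rosette_area == 0:
        return HueAbundance(plant_id=plant_id, day=day, fractions=None)
    k = k if k is not None else int(fg.max()) + 1
    counts = np.bincount(fg, minlength=k).astype(float)
    return HueAbundance(plant_id=plant_id, day=day, fractions=counts / rosette_area)


def abundance_table(records) -> pd.DataFrame:
    """Long-format table (plant_id, day, hue, fraction) from HueAbundance records."""
    rows = []
    for r in records:
        if r.missing:
            continue
        for h, f in enumerate(r.fractions, start=1):
            rows.append({"plant_id": r.plant_id, "day": r.day, "hue": h, "fraction": f})
    return pd.DataFrame(rows)


def hue_salt_ratio(
    abundance: pd.DataFrame,
    design_plants: pd.DataFrame,
    *,
    control_name: str = "control",
) -> pd.DataFrame:
    """Salt-induced change per accession/day/hue: mean salt fraction over
    mean control fraction.  A zero control mean flags the ratio as missing
    (NaN) rather than returning infinity; a missing treatment arm for an
    accession is an error.
    """
    merged = abundance.merge(
        design_plants[["plant_id", "accession", "treatment"]], on="plant_id", how="left"
    )
    out = []
    for (acc, day, hue), grp in merged.groupby(["accession", "day", "hue"]):
        ctrl = grp.loc[grp["treatment"] == control_name, "fraction"]
        salt_grp = grp[grp["treatment"] != control_name]
        if ctrl.empty or salt_grp.empty:
            raise ValueError(f"missing treatment arm for accession {acc} day {day}")
        for trt, sg in salt_grp.groupby("treatment"):
            cm = ctrl.mean()
            ratio = sg["fraction"].mean() / cm if cm > 0 else float("nan")
            out.append(
                {"accession": acc, "day": day, "hue": hue, "treatment": trt, "ratio": ratio}
            )
    return pd.DataFrame(out)
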