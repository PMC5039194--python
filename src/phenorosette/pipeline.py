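"""End-to-end orchestration: simulate -> segment -> morpho -> colors -> chlf
-> growth -> stats, glued together by CSV/PNG/YAML contracts on disk.

Stages communicate only through files under the configured output
directory, so each stage can also be run (and inspected) on its own.  One
merged long-format trait table (plant, day, state, trait, value) is the
final product, together with the growth/SIIT table, the hue palette and the
accession cluster report.  Per-plant failures are logged and skipped;
structural problems (bad config, missing directories) abort.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .chlf import CLUSTER_TRAITS, derive_parameters, extract_levels, get_protocol, relative_trait_table
from .color import abundance_table, build_hue_palette, collect_calibration_pixels, hue_abundance, segment_colors
from .growth import growth_table, siit
from .morpho import compute_morphometrics
from .rgb import SegmentationParams, TrayLayout, clean_mask, crop_tray, segment_rosette
from .stats import early_late_cluster_report
from .synthetic import (
    ExperimentDesign,
    Treatment,
    TrayStyle,
    assign_chlf_truth,
    assign_growth_truth,
    generate_design,
    render_tray_image,
    simulate_chlf_trace,
)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "phenorosette_run"
    seed: int = 0
    # experiment design
    accessions: list[str] = field(default_factory=lambda: ["Col-0", "C24"])
    treatments: list[dict] = field(
        default_factory=lambda: [{"name": "control", "nacl_mm": 0}, {"name": "salt", "nacl_mm": 100}]
    )
    n_replicates: int = 3
    days: list[int] = field(default_factory=lambda: list(range(8)))
    tray_rows: int = 4
    tray_cols: int = 5
    # imaging
    image_width: int = 640
    image_height: int = 480
    # segmentation
    exg_threshold: float = 30.0
    min_green: float = 40.0
    min_object_px: int = 20
    closing_radius: int = 1
    # colour palette
    palette_k: int = 9
    calibration_cap: int = 20000
    # fluorescence
    chlf_protocol: str = "light_curve"
    chlf_days: list[int] | None = None  # None = every design day
    chlf_noise_sd: float = 0.0
    chlf_sample_hz: float = 10.0
    # growth / SIIT
    intervals: list[list[int]] = field(default_factory=lambda: [[0, 3], [4, 7]])
    control_name: str = "control"
    # synthetic ground-truth model
    area0: float = 500.0
    gr_control: float = 150.0
    salt_ratio_early: float = 0.6
    salt_ratio_late: float = 0.5
    growth_cv: float = 0.05
    soil_noise_sd: float = 4.0
    leaf_jitter_sd: float = 0.0
    # stats
    row_clusters: int = 3
    col_clusters: int = 2

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.image_width % self.tray_cols or self.image_height % self.tray_rows:
            raise ValueError(
                f"image {self.image_width}x{self.image_height} not divisible into "
                f"{self.tray_rows}x{self.tray_cols} pot cells"
            )
        if self.chlf_protocol not in ("quenching", "light_curve"):
            raise ValueError(f"unknown ChlF protocol {self.chlf_protocol!r}")
        if len(self.intervals) != 2:
            raise ValueError("exactly two growth intervals are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    # -- derived helpers ----------------------------------------------------

    def design(self) -> ExperimentDesign:
        return generate_design(
            self.accessions,
            [Treatment(t["name"], t["nacl_mm"]) for t in self.treatments],
            self.n_replicates,
            self.days,
            tray_rows=self.tray_rows,
            tray_cols=self.tray_cols,
            seed=self.seed,
        )

    def seg_params(self) -> SegmentationParams:
        return SegmentationParams(
            exg_threshold=self.exg_threshold,
            min_green=self.min_green,
            min_object_px=self.min_object_px,
            closing_radius=self.closing_radius,
        )

    def chlf_day_list(self) -> list[int]:
        return list(self.days) if self.chlf_days is None else list(self.chlf_days)


def _p(base: Path, *parts) -> Path:
    out = base.joinpath(*parts)
    out.parent.mkdir(parents=True, exist_ok=True)
    return out


def simulate_experiment(cfg: PipelineConfig) -> dict:
    """Generate all raw inputs (tray images, traces, ground truth) on disk."""
    base = Path(cfg.out_dir)
    design = cfg.design()
    design.to_yaml(_p(base, "design.yaml"))
    design.plants.to_csv(_p(base, "plants.csv"), index=False)

    gtruth = assign_growth_truth(
        design,
        area0=cfg.area0,
        gr_control=cfg.gr_control,
        salt_ratio_early=cfg.salt_ratio_early,
        salt_ratio_late=cfg.salt_ratio_late,
        cv=cfg.growth_cv,
        seed=cfg.seed + 1,
    )
    gtruth.to_csv(_p(base, "truth", "growth_truth.csv"), index=False)

    style = TrayStyle(soil_noise_sd=cfg.soil_noise_sd, leaf_jitter_sd=cfg.leaf_jitter_sd)
    intervals = tuple(tuple(iv) for iv in cfg.intervals)
    truth_rows = []
    for day in cfg.days:
        for tray in range(design.n_trays):
            img, truths = render_tray_image(
                design, tray, day,
                growth_truth=gtruth, style=style, seed=cfg.seed + 2,
                image_size=(cfg.image_width, cfg.image_height), intervals=intervals,
            )
            pio.save_image(_p(base, "images", f"tray{tray:02d}_day{day:02d}.png"), img)
            for pid, t in truths.items():
                pio.save_mask(_p(base, "truth", "masks", f"{pid}_day{day:02d}.png"), t.mask)
                row = {"plant_id": pid, "day": day, "area_target": t.area_target, "area_px": t.area_px}
                if t.hue_fractions is not None:
                    row.update({f"hue_{i + 1}": f for i, f in enumerate(t.hue_fractions)})
                truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(_p(base, "truth", "truth.csv"), index=False)

    protocol = get_protocol(cfg.chlf_protocol)
    chlf_truth = assign_chlf_truth(design, seed=cfg.seed + 3)
    truth_param_rows = []
    for day in cfg.chlf_day_list():
        for p in design.plants.itertuples():
            trace, truth = simulate_chlf_trace(
                chlf_truth[p.plant_id], protocol,
                noise_sd=cfg.chlf_noise_sd,
                seed=(cfg.seed + 4, zlib.crc32(p.plant_id.encode()), day),
                sample_hz=cfg.chlf_sample_hz, plant_id=p.plant_id, day=day,
            )
            pio.save_trace_csv(_p(base, "traces", f"{p.plant_id}_day{day:02d}.csv"), trace)
            truth_param_rows.append(truth.parameters.to_long(p.plant_id, day))
    pd.concat(truth_param_rows, ignore_index=True).to_csv(_p(base, "truth", "chlf_truth.csv"), index=False)
    return {"n_plants": design.n_plants, "n_trays": design.n_trays}


def run_pipeline(cfg: PipelineConfig, *, simulate: bool = True) -> dict:
    """Execute every analysis stage; returns a summary with output paths.

    With ``simulate=True`` the raw inputs are generated first; otherwise
    they must already exist under ``cfg.out_dir`` in the simulate layout.
    Re-running with identical config and seed reproduces every output file
    byte for byte.
    """
    base = Path(cfg.out_dir)
    log: list[str] = []
    if simulate:
        simulate_experiment(cfg)

    design = ExperimentDesign.from_yaml(base / "design.yaml")
    layout = TrayLayout(rows=cfg.tray_rows, cols=cfg.tray_cols)
    seg = cfg.seg_params()

    # ---- segmentation: tray images -> per-pot masks + areas
    area_rows, masks, crops = [], {}, {}
    for day in cfg.days:
        for tray in range(design.n_trays):
            img = pio.load_image(base / "images" / f"tray{tray:02d}_day{day:02d}.png")
            pots = crop_tray(img, layout)
            for p in design.tray_plants(tray).itertuples():
                crop = pots[p.row * layout.cols + p.col]
                mask = clean_mask(segment_rosette(crop, seg), seg.min_object_px, seg.closing_radius)
                mask.plant_id, mask.day = p.plant_id, day
                pio.save_mask(_p(base, "masks", f"{p.plant_id}_day{day:02d}.png"), mask)
                masks[(p.plant_id, day)] = mask
                crops[(p.plant_id, day)] = crop
                area_rows.append({"plant_id": p.plant_id, "day": day, "area_px": mask.area_px})
    areas = pd.DataFrame(area_rows).sort_values(["plant_id", "day"]).reset_index(drop=True)
    areas.to_csv(_p(base, "areas.csv"), index=False)

    # ---- morphometrics
    morpho_rows = []
    for (pid, day), mask in sorted(masks.items()):
        if mask.area_px == 0:
            log.append(f"morpho: empty mask for {pid} day {day}; traits flagged missing")
            continue
        rec = compute_morphometrics(mask).as_dict()
        rec.update({"plant_id": pid, "day": day})
        morpho_rows.append(rec)
    morpho_df = pd.DataFrame(morpho_rows)
    morpho_df.to_csv(_p(base, "morphometrics.csv"), index=False)

    # ---- colour segmentation: global palette from start/middle/end.
    # Colour is read from vegetation-index-positive pixels inside the cleaned
    # mask: morphological closing exists for area/shape and may annex
    # soil-coloured pixels that would contaminate the hue scale.
    def veg_mask(pid, day):
        raw = segment_rosette(crops[(pid, day)], seg).mask
        return raw & masks[(pid, day)].mask

    cal_days = sorted({cfg.days[0], cfg.days[len(cfg.days) // 2], cfg.days[-1]})
    cal_pairs = [
        (crops[(pid, d)], veg_mask(pid, d))
        for d in cal_days
        for pid in design.plants["plant_id"]
        if masks[(pid, d)].area_px > 0
    ]
    pixels = collect_calibration_pixels(cal_pairs, cap_per_image=cfg.calibration_cap, seed=cfg.seed + 5)
    palette = build_hue_palette(pixels, k=cfg.palette_k, seed=cfg.seed + 6)
    palette.to_frame().to_csv(_p(base, "palette.csv"), index=False, float_format="%.6g")
    ab_records = []
    for (pid, day), mask in sorted(masks.items()):
        veg = veg_mask(pid, day)
        labels = segment_colors(crops[(pid, day)], veg, palette)
        ab_records.append(hue_abundance(labels, int(veg.sum()), plant_id=pid, day=day, k=palette.k))
    abundance = abundance_table(ab_records)
    abundance.to_csv(_p(base, "hue_abundance.csv"), index=False, float_format="%.9g")

    # ---- fluorescence parameters
    protocol = get_protocol(cfg.chlf_protocol)
    chlf_rows = []
    for day in cfg.chlf_day_list():
        for pid in design.plants["plant_id"]:
            path = base / "traces" / f"{pid}_day{day:02d}.csv"
            if not path.exists():
                log.append(f"chlf: missing trace for {pid} day {day}; flagged missing")
                continue
            try:
                trace = pio.load_trace_csv(path, plant_id=pid, day=day)
                params = derive_parameters(extract_levels(trace, protocol))
            except (ValueError, KeyError) as exc:
                log.append(f"chlf: {pid} day {day}: {exc}")
                continue
            chlf_rows.append(params.to_long(pid, day))
    chlf_long = (
        pd.concat(chlf_rows, ignore_index=True)
        if chlf_rows
        else pd.DataFrame(columns=["plant_id", "day", "state", "trait", "value"])
    )
    chlf_long.to_csv(_p(base, "chlf_parameters.csv"), index=False, float_format="%.9g")
    if not chlf_long.empty:
        # development+treatment fluctuations relative to the overall per-trait mean
        rel = relative_trait_table(chlf_long.dropna(subset=["value"]))
        rel.to_csv(_p(base, "chlf_parameters_relative.csv"), index=False, float_format="%.9g")

    # ---- growth + SIIT
    intervals = tuple(tuple(iv) for iv in cfg.intervals)
    growth = siit(growth_table(areas, design.plants, intervals), control_name=cfg.control_name)
    growth.to_csv(_p(base, "growth_siit.csv"), index=False, float_format="%.9g")

    # ---- merged long trait table
    long_parts = [
        areas.assign(state="", trait="area_px").rename(columns={"area_px": "value"}),
    ]
    if not morpho_df.empty:
        m_long = morpho_df.drop(columns=["area_px"]).melt(  # area already reported by the segmentation stage
            id_vars=["plant_id", "day"], var_name="trait", value_name="value"
        )
        long_parts.append(m_long.assign(state=""))
    if not abundance.empty:
        h_long = abundance.assign(trait=abundance["hue"].map(lambda h: f"hue_{h}"), state="")
        long_parts.append(h_long.rename(columns={"fraction": "value"})[["plant_id", "day", "state", "trait", "value"]])
    long_parts.append(chlf_long)
    traits_long = pd.concat(
        [p[["plant_id", "day", "state", "trait", "value"]] for p in long_parts], ignore_index=True
    ).sort_values(["plant_id", "day", "state", "trait"], kind="stable").reset_index(drop=True)
    traits_long.to_csv(_p(base, "traits_long.csv"), index=False, float_format="%.9g")

    # ---- accession-level salt-response clustering
    report = None
    if len(design.accessions) >= 2 and not chlf_long.empty:
        matrix = accession_salt_response_matrix(
            chlf_long, growth, design.plants,
            state=protocol.steady_state, day=cfg.chlf_day_list()[-1],
            control_name=cfg.control_name,
        )
        matrix.to_csv(_p(base, "cluster_matrix.csv"), float_format="%.9g")
        try:
            report = early_late_cluster_report(
                matrix, row_clusters=min(cfg.row_clusters, len(matrix)), col_clusters=cfg.col_clusters
            )
            pd.DataFrame(
                {"accession": report.rows.leaf_names, "cluster": [report.rows.labels[a] for a in report.rows.leaf_names]}
            ).to_csv(_p(base, "accession_clusters.csv"), index=False)
            report.matrix_std.to_csv(_p(base, "heatmap_matrix.csv"), float_format="%.9g")
        except ValueError as exc:
            log.append(f"stats: clustering skipped: {exc}")

    manifest = {
        "package": "phenorosette",
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(yaml.safe_dump(asdict(cfg), sort_keys=True).encode()).hexdigest(),
        "n_plants": design.n_plants,
        "n_flagged": len(log),
        "warnings": log,
    }
    with open(_p(base, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"traits_long": base / "traits_long.csv", "manifest": manifest, "report": report}


def accession_salt_response_matrix(
    chlf_long: pd.DataFrame,
    growth: pd.DataFrame,
    design_plants: pd.DataFrame,
    *,
    state: str,
    day: int,
    control_name: str = "control",
) -> pd.DataFrame:
    """Accessions x (8 fluorescence traits + SIIT1/2), salt relative to control.

    Fluorescence traits are taken at the given state and day (Fv/Fm from its
    dark-adapted record of the same run) and expressed as mean(salt) /
    mean(control) per accession; SIIT values are accession means.
    """
    df = chlf_long.merge(design_plants[["plant_id", "accession", "treatment"]], on="plant_id")
    df = df[df["day"] == day]
    rows = {}
    for acc, grp in df.groupby("accession"):
        rec = {}
        for trait in CLUSTER_TRAITS:
            sel = grp[(grp["trait"] == trait) & (grp["state"].isin([state, "dark"]))]
            ctrl = sel.loc[sel["treatment"] == control_name, "value"].mean()
            salt = sel.loc[sel["treatment"] != control_name, "value"].mean()
            rec[trait] = salt / ctrl if ctrl and np.isfinite(ctrl) else np.nan
        rows[acc] = rec
    matrix = pd.DataFrame(rows).T
    sii = growth[growth["treatment"] != control_name].groupby("accession")[["SIIT1", "SIIT2"]].mean()
    matrix = matrix.join(sii)
    matrix.index.name = "accession"
    return matrix[list(CLUSTER_TRAITS) + ["SIIT1", "SIIT2"]]
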