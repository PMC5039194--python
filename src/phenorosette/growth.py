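"""Two-interval growth rates and the shoot ion-independent tolerance index.

The projected rosette area of each plant is fitted with an ordinary
least-squares line over two configurable day intervals (closed on both
ends).  The slope is the growth rate GR (px/day).  For salt-treated plants
the SIIT index is the plant's GR divided by the mean control GR of the same
accession over the same interval: SIIT₁ for the early (osmotic) phase,
SIIT₂ for the late phase.  Negative fitted slopes — shrinking rosettes —
are clipped to zero and flagged rather than yielding negative tolerance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic.growth import INTERVALS_NATURAL, INTERVALS_PROTOCOL  # noqa: F401  (re-export)


def fit_growth_rate(days, areas, interval) -> dict:
    """OLS slope of area vs day inside the closed interval.

    Returns {gr, intercept, r2, n_points, flag}.  Fewer than two distinct
    days inside the interval gives a flagged missing value; two or more
    observations on a single day is an error.
    """
    days = np.asarray(days, float)
    areas = np.asarray(areas, float)
    lo, hi = interval
    sel = (days >= lo) & (days <= hi) & np.isfinite(areas)
    x, y = days[sel], areas[sel]
    if x.size < 2:
        return {"gr": np.nan, "intercept": np.nan, "r2": np.nan, "n_points": int(x.size), "flag": "too_few_points"}
    if np.unique(x).size < 2:
        raise ValueError(f"all {x.size} observations fall on day {x[0]:g}; cannot fit a slope")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"gr": float(slope), "intercept": float(intercept), "r2": r2, "n_points": int(x.size), "flag": ""}


def growth_table(
    areas: pd.DataFrame,
    design_plants: pd.DataFrame,
    intervals=INTERVALS_PROTOCOL,
) -> pd.DataFrame:
    """Per-plant GR_early / GR_late from a (plant_id, day, area_px) table."""
    merged = areas.merge(design_plants[["plant_id", "accession", "treatment", "nacl_mm"]], on="plant_id")
    rows = []
    for pid, grp in merged.groupby("plant_id", sort=True):
        rec = {
            "plant_id": pid,
            "accession": grp["accession"].iloc[0],
            "treatment": grp["treatment"].iloc[0],
            "nacl_mm": grp["nacl_mm"].iloc[0],
        }
        for name, iv in zip(("early", "late"), intervals):
            fit = fit_growth_rate(grp["day"], grp["area_px"], iv)
            rec[f"gr_{name}"] = fit["gr"]
            rec[f"r2_{name}"] = fit["r2"]
            rec[f"flag_{name}"] = fit["flag"]
        rows.append(rec)
    return pd.DataFrame(rows)


def siit(
    growth: pd.DataFrame,
    *,
    control_name: str = "control",
    clip_negative: bool = True,
) -> pd.DataFrame:
    """Append SIIT1/SIIT2 columns to a growth table.

    SIIT is computed per salt-treated plant as GR / mean(control GR of the
    same accession and interval); control rows keep NaN.  A non-positive
    control mean flags the index as missing.
    """
    out = growth.copy()
    for name, col in (("SIIT1", "gr_early"), ("SIIT2", "gr_late")):
        gr = out[col].astype(float)
        if clip_negative:
            neg = gr < 0
            gr = gr.clip(lower=0.0)
            out.loc[neg, f"flag_{col.split('_')[1]}"] = "negative_gr_clipped"
        ctrl_mean = (
            out[out["treatment"] == control_name]
            .assign(gr=gr[out["treatment"] == control_name])
            .groupby("accession")["gr"]
            .mean()
        )
        vals = np.full(len(out), np.nan)
        for i, row in enumerate(out.itertuples()):
            if row.treatment == control_name:
                continue
            cm = ctrl_mean.get(row.accession, np.nan)
            if not np.isfinite(cm):
                raise ValueError(f"no control plants with valid GR for accession {row.accession}")
            vals[i] = gr.iloc[i] / cm if cm > 0 else np.nan
        out[name] = vals
    return out
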