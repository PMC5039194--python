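"""Piecewise-linear rosette growth simulator.

Projected rosette area grows linearly in an early and a late phase, the
same two-interval model the growth-rate fitting stage assumes.  The early
slope applies up to the end of the first interval; the late slope applies
afterwards (including any gap days between the two fitting intervals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: fitting intervals (days) used when the protocol was developed ...
INTERVALS_PROTOCOL = ((0, 4), (7, 11))
#: ... and when natural variation across accessions was screened.
INTERVALS_NATURAL = ((0, 3), (4, 7))


def _check_intervals(intervals) -> tuple[tuple[int, int], tuple[int, int]]:
    (a0, a1), (b0, b1) = intervals
    if a1 < a0 or b1 < b0:
        raise ValueError(f"intervals must be ordered (lo, hi): {intervals}")
    if not (a1 < b0 or b1 < a0):
        raise ValueError(f"growth intervals overlap: {intervals}")
    if a0 > b0:  # normalise to early-first
        (a0, a1), (b0, b1) = (b0, b1), (a0, a1)
    return (a0, a1), (b0, b1)


def area_at(day, area0: float, gr_early: float, gr_late: float, intervals=INTERVALS_PROTOCOL):
    """Noise-free area at ``day``: slope ``gr_early`` through the end of the
    first interval, ``gr_late`` after it.  Clipped at zero."""
    (a0, a1), _ = _check_intervals(intervals)
    day = np.asarray(day, dtype=float)
    early_span = np.minimum(day, a1) - a0
    late_span = np.maximum(day - a1, 0.0)
    return np.maximum(area0 + gr_early * early_span + gr_late * late_span, 0.0)


def simulate_growth_series(
    gr_early: float,
    gr_late: float,
    intervals=INTERVALS_PROTOCOL,
    *,
    area0: float = 50.0,
    days=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-day projected area with additive Gaussian noise (px units).

    Returns a DataFrame with columns day, area_px.  Areas are clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    intervals = _check_intervals(intervals)
    if days is None:
        days = list(range(intervals[0][0], intervals[1][1] + 1))
    days = np.asarray(sorted(int(d) for d in days))
    rng = np.random.default_rng(seed)
    area = area_at(days, area0, gr_early, gr_late, intervals)
    if noise_sd > 0:
        area = area + rng.normal(0.0, noise_sd, size=area.shape)
    return pd.DataFrame({"day": days, "area_px": np.maximum(area, 0.0)})


@dataclass(frozen=True)
class GrowthTruth:
    """Ground-truth growth parameters for one plant."""

    plant_id: str
    area0: float
    gr_early: float
    gr_late: float


def assign_growth_truth(
    design,
    *,
    area0: float = 2000.0,
    gr_control: float = 600.0,
    salt_ratio_early: float = 0.6,
    salt_ratio_late: float = 0.5,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-plant true growth rates for an experiment design.

    Control plants grow at ``gr_control`` px/day (both phases); salt-treated
    plants at ``salt_ratio_early/late`` times that, mirroring the osmotic-phase
    growth penalty the SIIT index quantifies.  Per-plant lognormal-ish jitter
    with coefficient of variation ``cv``.  Stronger NaCl doses scale the
    penalty: the ratio applies per 100 mM, linearly interpolated.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in design.plants.itertuples():
        dose = p.nacl_mm / 100.0
        re = 1.0 - dose * (1.0 - salt_ratio_early)
        rl = 1.0 - dose * (1.0 - salt_ratio_late)
        re, rl = max(re, 0.05), max(rl, 0.05)
        jitter = rng.normal(1.0, cv, size=3)
        rows.append(
            {
                "plant_id": p.plant_id,
                "area0": max(area0 * jitter[0], 1.0),
                "gr_early": max(gr_control * re * jitter[1], 0.0),
                "gr_late": max(gr_control * rl * jitter[2], 0.0),
            }
        )
    return pd.DataFrame(rows)
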