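"""Experiment bookkeeping: accessions x treatments x replicates x days.

The design is the spine that every trait table joins against.  Each plant
gets a stable identifier and a fixed (tray, row, col) slot; trays hold
``rows * cols`` pots (default 4 x 5 = 20) and the last tray may be partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

DEFAULT_TRAY_ROWS = 4
DEFAULT_TRAY_COLS = 5

#: NaCl concentrations (mM) used in the watering regimes; 0 = control.
VALID_NACL_MM = (0, 50, 100, 150)


@dataclass(frozen=True)
class Treatment:
    name: str
    nacl_mm: int = 0

    def __post_init__(self) -> None:
        if self.nacl_mm not in VALID_NACL_MM:
            raise ValueError(
                f"nominal NaCl must be one of {VALID_NACL_MM} mM, got {self.nacl_mm}"
            )


@dataclass
class ExperimentDesign:
    """Accessions x treatments x replicates laid out on trays over days.

    ``plants`` is a DataFrame with one row per plant:
    plant_id, accession, treatment, nacl_mm, replicate, tray, row, col.
    """

    accessions: list[str]
    treatments: list[Treatment]
    n_replicates: int
    days: list[int]
    tray_rows: int = DEFAULT_TRAY_ROWS
    tray_cols: int = DEFAULT_TRAY_COLS
    seed: int = 0
    plants: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_trays(self) -> int:
        return int(self.plants["tray"].max()) + 1 if self.n_plants else 0

    @property
    def slots_per_tray(self) -> int:
        return self.tray_rows * self.tray_cols

    def tray_plants(self, tray_index: int) -> pd.DataFrame:
        """Plants sitting on one tray, in row-major slot order."""
        sub = self.plants[self.plants["tray"] == tray_index]
        if sub.empty:
            raise ValueError(f"tray {tray_index} does not exist (0..{self.n_trays - 1})")
        return sub.sort_values(["row", "col"]).reset_index(drop=True)

    def to_yaml(self, path) -> None:
        doc = {
            "accessions": list(self.accessions),
            "treatments": [{"name": t.name, "nacl_mm": t.nacl_mm} for t in self.treatments],
            "n_replicates": self.n_replicates,
            "days": list(self.days),
            "tray_rows": self.tray_rows,
            "tray_cols": self.tray_cols,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return generate_design(
            accessions=doc["accessions"],
            treatments=[Treatment(t["name"], t["nacl_mm"]) for t in doc["treatments"]],
            n_replicates=doc["n_replicates"],
            days=doc["days"],
            tray_rows=doc.get("tray_rows", DEFAULT_TRAY_ROWS),
            tray_cols=doc.get("tray_cols", DEFAULT_TRAY_COLS),
            seed=doc.get("seed", 0),
        )


def generate_design(
    accessions,
    treatments,
    n_replicates: int,
    days,
    *,
    tray_rows: int = DEFAULT_TRAY_ROWS,
    tray_cols: int = DEFAULT_TRAY_COLS,
    seed: int = 0,
) -> ExperimentDesign:
    """Build a randomized experiment design.

    Plants (every accession x treatment x replicate combination) are shuffled
    with the seeded generator and assigned to tray slots in row-major order,
    so treatments are interleaved across trays as they would be on a real
    phenotyping platform.  Deterministic for a fixed seed.
    """
    accessions = [str(a) for a in accessions]
    if isinstance(treatments, int):
        raise TypeError("treatments must be a list of Treatment, not a count")
    treatments = [t if isinstance(t, Treatment) else Treatment(*t) for t in treatments]
    days = [int(d) for d in days]
    if not accessions or not treatments:
        raise ValueError("need at least one accession and one treatment")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    if tray_rows < 1 or tray_cols < 1:
        raise ValueError("tray layout dimensions must be positive")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")

    rows = []
    for acc in accessions:
        for tr in treatments:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "plant_id": f"{acc}_{tr.name}_r{rep:02d}",
                        "accession": acc,
                        "treatment": tr.name,
                        "nacl_mm": tr.nacl_mm,
                        "replicate": rep,
                    }
                )
    plants = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(plants))
    plants = plants.iloc[order].reset_index(drop=True)

    slots = tray_rows * tray_cols
    idx = np.arange(len(plants))
    plants["tray"] = idx // slots
    plants["row"] = (idx % slots) // tray_cols
    plants["col"] = (idx % slots) % tray_cols

    return ExperimentDesign(
        accessions=accessions,
        treatments=treatments,
        n_replicates=n_replicates,
        days=days,
        tray_rows=tray_rows,
        tray_cols=tray_cols,
        seed=seed,
        plants=plants,
    )
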