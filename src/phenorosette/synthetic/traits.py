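"""Accession-level trait archetypes for clustering experiments.

Generates an accessions x traits salt-response matrix (eight fluorescence
traits plus SIIT1/SIIT2, all as salt-relative-to-control ratios) from a
small number of archetype profiles, with per-accession Gaussian noise.
Used to test whether Ward clustering recovers known group structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..chlf import CLUSTER_TRAITS

TRAIT_ORDER = tuple(CLUSTER_TRAITS) + ("SIIT1", "SIIT2")

#: salt-relative trait profiles: a tolerant archetype (growth and
#: photochemistry barely affected) and a sensitive one (strong growth
#: penalty, elevated non-photochemical quenching, depressed quantum yields)
ARCHETYPE_TOLERANT = {
    "FvFm": 0.98, "FvpFmp": 0.97, "PhiP": 0.95, "qP": 0.96,
    "PhiNO": 1.02, "PhiNPQ": 1.08, "qN": 1.05, "NPQ": 1.10,
    "SIIT1": 0.85, "SIIT2": 0.75,
}
ARCHETYPE_SENSITIVE = {
    "FvFm": 0.90, "FvpFmp": 0.80, "PhiP": 0.65, "qP": 0.70,
    "PhiNO": 1.15, "PhiNPQ": 1.45, "qN": 1.35, "NPQ": 1.60,
    "SIIT1": 0.45, "SIIT2": 0.35,
}


def simulate_accession_traits(
    n_accessions: int = 8,
    archetypes=(ARCHETYPE_TOLERANT, ARCHETYPE_SENSITIVE),
    *,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw accessions from archetype profiles (round-robin assignment).

    Returns (matrix, true_labels): matrix is accessions x traits with
    additive Gaussian noise of SD ``noise_sd`` on every entry; true_labels
    gives the generating archetype index per accession.
    """
    if n_accessions < len(archetypes):
        raise ValueError("need at least one accession per archetype")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_accessions) % len(archetypes)
    rows = []
    for i, lab in enumerate(labels):
        prof = archetypes[lab]
        rows.append({t: prof[t] + rng.normal(0.0, noise_sd) for t in TRAIT_ORDER})
    idx = [f"acc{i + 1:02d}" for i in range(n_accessions)]
    return pd.DataFrame(rows, index=idx)[list(TRAIT_ORDER)], labels
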