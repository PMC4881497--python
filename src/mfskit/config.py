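"""Run-time configuration shared by all mfskit stages.

Every numeric constant of the extraction / superposition / clustering
pipeline lives here so that outputs can embed the full effective
configuration for provenance.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

logger = logging.getLogger("mfskit")

#: Weights (w1, w2, w3) of the three superposition-score terms
#: (fragmentation, coverage, biochemical similarity).  Calibrated on
#: synthetic panels by ``scripts/calibrate_weights.py`` so that
#: near-duplicate sites fall at or below the stringent 2.25 threshold
#: and unrelated sites above 3.0 (see docs/methods.md).
DEFAULT_WEIGHTS: tuple[float, float, float] = (2.75, 2.75, 2.75)

#: Per-metal minimum donor-atom counts used to filter out adventitious
#: surface sites before computing site statistics.
DEFAULT_MIN_DONORS: dict[str, int] = {"Zn": 3, "Fe": 4, "Ca": 4, "Cu": 2}


@dataclass(frozen=True)
class Config:
    """All tunable thresholds of the pipeline (distances in Angstrom)."""

    # --- donor detection -------------------------------------------------
    donor_pad: float = 0.5          # added to the covalent-radius sum
    donor_cap: float = 3.0          # hard upper bound on any donor cutoff
    donor_elements: tuple[str, ...] = ("N", "O", "S", "Cl", "Br", "I", "Se", "P", "F")
    # --- site assembly / environment -------------------------------------
    merge_cutoff: float = 5.0       # metal-metal merge distance (strict <)
    neighbor_cutoff: float = 5.0    # ligand-to-environment distance (strict <)
    # --- superposition ----------------------------------------------------
    ca_threshold: float = 2.0       # CA-CA (C1'-C1') matching threshold
    ligand_ca_threshold: float = 5.0  # relaxed threshold for metal ligands
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    top_k: int = 10                 # poses refined after the initial ranking
    pose_dedup_tol: float = 1e-6
    # --- clustering --------------------------------------------------------
    intra_threshold: float = 2.25   # stringent, complete linkage
    inter_threshold: float = 2.75   # relaxed, average linkage
    center_distance_cutoff: float = 3.5   # equistructural center criterion
    identity_cutoff: float = 50.0   # % chain identity for equistructural pairs
    # --- statistics --------------------------------------------------------
    min_donors: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_DONORS)
    )
    default_min_donors: int = 1     # for metals not in the map
    # --- metal classification ---------------------------------------------
    extra_metals: tuple[str, ...] = ()      # user additions (e.g. metalloids)
    excluded_metals: tuple[str, ...] = ()   # user removals

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["min_donors"] = dict(self.min_donors)
        return d

    def replace(self, **kw) -> "Config":
        return dataclasses.replace(self, **kw)


DEFAULT_CONFIG = Config()
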