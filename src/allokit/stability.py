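"""Tier-III pose-stability triage.

Each hit-receptor complex is simulated and the ligand's heavy-atom RMSD
from its initial docked pose is tracked after superposing every frame onto
the first on receptor CA atoms (the ligand itself is never refit, so the
series measures real pose drift).  A 3 A threshold separates stable from
drifting frames; the fraction of frames below threshold maps a trace to
one of three classes, and the final hits are the compounds called highly
stable against both the wild-type and mutant receptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geometry import superpose
from .structio import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "LigandRmsdSeries",
    "StabilityCall",
    "STABILITY_RMSD_THRESHOLD",
    "ligand_rmsd_series",
    "classify_stability",
    "consensus_stability",
]

#: Ligand-RMSD stability criterion, Angstrom.
STABILITY_RMSD_THRESHOLD = 3.0
#: Class boundaries on the fraction of frames below threshold.
DEFAULT_F_HI = 0.90
DEFAULT_F_LO = 0.50

CLASSES = ("highly_stable", "partially_stable", "unstable")


@dataclass
class LigandRmsdSeries:
    """Per-frame ligand heavy-atom RMSD vs the initial docked pose (A)."""

    compound_id: str
    receptor_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) == 0:
            raise ValueError("empty RMSD series")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def ligand_rmsd_series(
    traj: Trajectory,
    ligand_res_name: str = "LIG",
    compound_id: str = "ligand",
    receptor_id: str = "receptor",
) -> LigandRmsdSeries:
    """Ligand RMSD per frame after receptor-CA superposition to frame 1.

    The ligand is identified by residue name; its heavy atoms are compared
    to their frame-1 positions without any ligand refit.  No
    graph-automorphism symmetry correction is applied.
    """
    top = traj.topology
    lig_mask = (top.res_name == ligand_res_name) & ~np.isin(top.element, ["H", "D"])
    lig_idx = np.flatnonzero(lig_mask)
    if len(lig_idx) == 0:
        raise KeyError(f"no ligand atoms with res_name {ligand_res_name!r}")
    rec_ca = np.flatnonzero(
        (top.res_name != ligand_res_name) & (top.name == "CA") & (top.element == "C")
    )
    if len(rec_ca) < 3:
        raise ValueError("fewer than 3 receptor CA atoms for superposition")
    ref_ca = traj.frames[0, rec_ca, :]
    ref_lig = traj.frames[0, lig_idx, :]
    values = np.empty(traj.n_frames)
    values[0] = 0.0
    for i in range(1, traj.n_frames):
        if not np.all(np.isfinite(traj.frames[i, lig_idx, :])):
            raise ValueError(f"ligand coordinates missing/non-finite in frame {i + 1}")
        sp = superpose(traj.frames[i, rec_ca, :], ref_ca)
        lig_fitted = sp.apply(traj.frames[i, lig_idx, :])
        values[i] = float(np.sqrt(((lig_fitted - ref_lig) ** 2).sum(1).mean()))
    return LigandRmsdSeries(
        compound_id=compound_id, receptor_id=receptor_id, values=values
    )


@dataclass
class StabilityCall:
    compound_id: str
    receptor_id: str
    klass: str  # highly_stable | partially_stable | unstable
    fraction_below_threshold: float

    def __post_init__(self):
        if self.klass not in CLASSES:
            raise ValueError(f"unknown stability class {self.klass!r}")
        if not 0.0 <= self.fraction_below_threshold <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


def classify_stability(
    s: LigandRmsdSeries,
    threshold: float = STABILITY_RMSD_THRESHOLD,
    f_hi: float = DEFAULT_F_HI,
    f_lo: float = DEFAULT_F_LO,
) -> StabilityCall:
    """Three-class call from the fraction of frames with RMSD < threshold.

    p >= f_hi -> highly_stable; p < f_lo -> unstable; otherwise
    partially_stable.  The 3 A threshold is the stability criterion; the
    fraction boundaries (0.90/0.50) are this package's operationalization
    of the three classes and are configurable.
    """
    p = float(np.mean(s.values < threshold))
    if p >= f_hi:
        klass = "highly_stable"
    elif p < f_lo:
        klass = "unstable"
    else:
        klass = "partially_stable"
    return StabilityCall(
        compound_id=s.compound_id,
        receptor_id=s.receptor_id,
        klass=klass,
        fraction_below_threshold=p,
    )


def consensus_stability(
    calls_wt: Sequence[StabilityCall] | Mapping[str, StabilityCall],
    calls_mt: Sequence[StabilityCall] | Mapping[str, StabilityCall],
) -> list[str]:
    """Compounds called highly stable against both receptor states, sorted.

    Ids present in only one call set are excluded with a warning.
    """

    def _as_map(calls) -> dict[str, StabilityCall]:
        if isinstance(calls, Mapping):
            return dict(calls)
        return {c.compound_id: c for c in calls}

    wt = _as_map(calls_wt)
    mt = _as_map(calls_mt)
    only = set(wt) ^ set(mt)
    if only:
        logger.warning("compounds present in one call set only, excluded: %s",
                       sorted(only))
    shared = set(wt) & set(mt)
    return sorted(
        c for c in shared
        if wt[c].klass == "highly_stable" and mt[c].klass == "highly_stable"
    )


def calls_to_frame(calls: Sequence[StabilityCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "compound_id": c.compound_id,
                "receptor_id": c.receptor_id,
                "class": c.klass,
                "fraction_below_threshold": c.fraction_below_threshold,
            }
            for c in calls
        ]
    )
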