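"""Multi-tier virtual-screening logic: pre-filter, ranking, consensus.

Tier I docks a pre-filtered library against the apo closed receptor and
keeps the top-N by theoretical binding affinity (t-BA).  Tier II docks the
survivors against two inhibitor-bound closed receptors and selects hits by
progressive consensus over the two ranked lists (common compounds at depth
20, then 40, 60, 80, 100).  Computationally selected (t-BA) hits are merged
with a manually curated (h-VI, human-visualized interaction) list, Tier III
molecular-dynamics jobs are planned for every hit x receptor pair, and a
cross-docking check against the known SHP099 tunnel site flags compounds
that might compete with the reference inhibitor there.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .structio import CompoundRecord, ScoreTable, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "ConsensusResult",
    "FilterReport",
    "DockingBackend",
    "MockDockingBackend",
    "NON_METALS",
    "prefilter",
    "rank",
    "progressive_consensus",
    "merge_hit_sets",
    "plan_tier3",
    "crosscheck_site1",
    "DEFAULT_CONSENSUS_SCHEDULE",
    "SHP099_REFERENCE_AFFINITY",
]

#: Elements counted as non-metals for the metal-stripping rule.
NON_METALS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

DEFAULT_MW_MAX = 700.0  # Da
DEFAULT_ABS_CHARGE_MAX = 1  # a.u.
DEFAULT_TIER1_TOP_N = 2000
DEFAULT_CONSENSUS_SCHEDULE = (20, 40, 60, 80, 100)
#: Docking affinity of SHP099 in its crystallographic pose, kcal/mol.
SHP099_REFERENCE_AFFINITY = -13.0


@dataclass
class FilterReport:
    """Outcome of the library pre-filter: kept + rejected = input."""

    kept: list[str]
    rejected: dict[str, str]  # id -> first failing rule
    all_reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"compound_id": c, "kept": True, "reason": ""} for c in self.kept]
        rows += [
            {"compound_id": c, "kept": False, "reason": r}
            for c, r in self.rejected.items()
        ]
        return pd.DataFrame(rows)


def prefilter(
    lib: Sequence[CompoundRecord],
    mw_max: float = DEFAULT_MW_MAX,
    abs_charge_max: int = DEFAULT_ABS_CHARGE_MAX,
    non_metals: frozenset[str] = NON_METALS,
) -> FilterReport:
    """Apply the three library pre-screen rules.

    A compound is kept iff it contains no metal element, its molecular
    weight is at most ``mw_max`` Da (inclusive), and its absolute net formal
    charge is at most ``abs_charge_max`` a.u.  ``rejected`` records the
    first failing rule (metal, then mol_weight, then net_charge);
    ``all_reasons`` records every failing rule per compound.
    """
    kept: list[str] = []
    rejected: dict[str, str] = {}
    all_reasons: dict[str, list[str]] = {}
    for rec in lib:
        for attr in ("id", "mol_weight", "net_charge", "elements"):
            if getattr(rec, attr, None) is None:
                raise ValueError(f"compound record missing field {attr!r}: {rec!r}")
        reasons = []
        if any(el not in non_metals for el in rec.elements):
            reasons.append("metal")
        if rec.mol_weight > mw_max:
            reasons.append("mol_weight")
        if abs(rec.net_charge) > abs_charge_max:
            reasons.append("net_charge")
        if reasons:
            rejected[rec.id] = reasons[0]
            all_reasons[rec.id] = reasons
        else:
            kept.append(rec.id)
    return FilterReport(kept=kept, rejected=rejected, all_reasons=all_reasons)


@dataclass
class RankedList:
    """Compounds ordered by best-pose affinity (rank 1 = most negative)."""

    receptor_id: str
    compound_ids: list[str]
    affinities: dict[str, float]

    def __post_init__(self):
        vals = [self.affinities[c] for c in self.compound_ids]
        if any(nxt < prev for prev, nxt in zip(vals, vals[1:])):
            raise ValueError("ranked affinities must be non-decreasing")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids in ranked list")

    def top(self, n: int) -> list[str]:
        return self.compound_ids[:n]

    def __len__(self) -> int:
        return len(self.compound_ids)


def rank(st: ScoreTable, receptor_id: str) -> RankedList:
    """Rank compounds for one receptor by best-pose affinity.

    Most negative affinity first; ties broken lexicographically by id.
    """
    best = st.best_pose(receptor_id)
    ordered = best.sort_values(
        ["affinity", "compound_id"], kind="mergesort"
    )
    ids = ordered["compound_id"].tolist()
    return RankedList(
        receptor_id=receptor_id,
        compound_ids=ids,
        affinities=dict(zip(ordered["compound_id"], ordered["affinity"].astype(float))),
    )


@dataclass
class ConsensusResult:
    """Progressive-consensus hits with the depth at which each entered."""

    hits: list[tuple[str, int]]  # (compound_id, depth)
    schedule: tuple[int, ...]

    @property
    def ids(self) -> list[str]:
        return [c for c, _ in self.hits]

    def at_depth(self, d: int) -> list[str]:
        return [c for c, dep in self.hits if dep == d]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.hits, columns=["compound_id", "depth"])


def progressive_consensus(
    A: RankedList,
    B: RankedList,
    schedule: Sequence[int] = DEFAULT_CONSENSUS_SCHEDULE,
) -> ConsensusResult:
    """Common compounds of two ranked lists at increasing depths.

    At each depth d the intersection of both top-d prefixes is taken and
    compounds not already selected are added, labelled d.  The final hit
    set therefore equals the plain intersection of the two top-max(d)
    prefixes; the depth label is the smallest scheduled depth at which both
    lists contain the compound.
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("ranked lists must be non-empty")
    schedule = tuple(schedule)
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly increasing")
    max_d = schedule[-1]
    if len(A) < max_d or len(B) < max_d:
        logger.warning(
            "ranked list shorter than max depth %d (A=%d, B=%d); truncating",
            max_d, len(A), len(B),
        )
    hits: list[tuple[str, int]] = []
    selected: set[str] = set()
    for d in schedule:
        common = set(A.top(d)) & set(B.top(d))
        new = sorted(common - selected)
        hits.extend((c, d) for c in new)
        selected |= common
    return ConsensusResult(hits=hits, schedule=schedule)


@dataclass
class MergedHits:
    """Union of computed (t-BA) and curated (h-VI) hit sets with provenance."""

    ids: list[str]
    provenance: dict[str, str]  # id -> "t-BA" | "h-VI" | "both"
    overlap: int

    def __len__(self) -> int:
        return len(self.ids)


def merge_hit_sets(tba: Sequence[str], hvi: Sequence[str]) -> MergedHits:
    """Merge affinity-selected and visually curated hit lists."""
    tba_set, hvi_set = set(tba), set(hvi)
    both = tba_set & hvi_set
    provenance = {
        c: ("both" if c in both else ("t-BA" if c in tba_set else "h-VI"))
        for c in tba_set | hvi_set
    }
    return MergedHits(
        ids=sorted(tba_set | hvi_set),
        provenance=provenance,
        overlap=len(both),
    )


@dataclass(frozen=True)
class Tier3Job:
    compound_id: str
    receptor_id: str
    pocket: str = "allo_closite"
    duration_ns: float = 100.0


def plan_tier3(
    hits: Sequence[str],
    receptors: Sequence[str],
    pocket: str = "allo_closite",
    duration_ns: float = 100.0,
) -> list[Tier3Job]:
    """Plan one MD stability run per (receptor, hit) pair.

    Deterministic order: receptor-major, compounds lexicographic.  39 hits
    against the wild-type and mutant receptors yields 78 jobs.
    """
    if not hits or not receptors:
        raise ValueError("hits and receptors must be non-empty")
    return [
        Tier3Job(compound_id=c, receptor_id=r, pocket=pocket, duration_ns=duration_ns)
        for r in receptors
        for c in sorted(hits)
    ]


@dataclass
class CrossCheckResult:
    flags: dict[str, bool]  # id -> competitive with the reference inhibitor
    reference_affinity: float
    margin: float

    @property
    def n_competitive(self) -> int:
        return sum(self.flags.values())


def crosscheck_site1(
    hits: Sequence[str],
    st: ScoreTable,
    receptor_id: str | None = None,
    reference_affinity: float = SHP099_REFERENCE_AFFINITY,
    margin: float = 2.0,
) -> CrossCheckResult:
    """Compare hit affinities at the known tunnel site with SHP099's.

    A hit is competitive iff its affinity is at least as favourable as
    ``reference_affinity + margin`` (both kcal/mol, more negative is
    stronger).  With the -13 kcal/mol reference and a 2 kcal/mol margin, a
    compound must dock at -11 or better to be flagged.
    """
    if receptor_id is None:
        receptors = st.receptors
        if len(receptors) != 1:
            raise ValueError(
                f"score table has receptors {receptors}; pass receptor_id"
            )
        receptor_id = receptors[0]
    best = st.best_pose(receptor_id).set_index("compound_id")["affinity"]
    missing = [c for c in hits if c not in best.index]
    if missing:
        raise KeyError(f"hits missing from site-1 score table: {missing}")
    flags = {
        c: bool(best[c] <= reference_affinity + margin) for c in sorted(hits)
    }
    return CrossCheckResult(
        flags=flags, reference_affinity=reference_affinity, margin=margin
    )


# ---------------------------------------------------------------------------
# Docking backend contract


class DockingBackend(Protocol):
    """Adapter contract for an external docking engine."""

    def score(
        self,
        receptor: Structure | str,
        compound: CompoundRecord | str,
        box_center: tuple[float, float, float],
        box_size: tuple[float, float, float],
    ) -> tuple[float, object]:
        """Return (affinity kcal/mol, pose)."""
        ...


class MockDockingBackend:
    """Deterministic stand-in backend: a pure function of ids and seed.

    Affinities are drawn from N(-7, 1) keyed by a stable hash of
    (receptor id, compound id, seed); poses are None.  Useful for pipeline
    wiring and tests, not for chemistry.
    """

    def __init__(self, seed: int = 0, mean: float = -7.0, sigma: float = 1.0):
        self.seed = seed
        self.mean = mean
        self.sigma = sigma

    def score(self, receptor, compound, box_center=None, box_size=None):
        rid = receptor if isinstance(receptor, str) else "receptor"
        cid = compound if isinstance(compound, str) else compound.id
        key = f"{rid}|{cid}|{self.seed}".encode()
        digest = hashlib.sha256(key).digest()
        sub_seed = int.from_bytes(digest[:4], "big")
        rng = np.random.default_rng(sub_seed)
        return float(self.mean + self.sigma * rng.standard_normal()), None
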