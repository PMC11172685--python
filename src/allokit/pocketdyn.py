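"""Allosteric pocket definitions and trajectory-level pocket analytics.

SHP2 carries two known allosteric inhibitor sites and a cryptic third pocket
at the three-domain junction:

* ``allo_site_1`` — the SHP099 tunnel at the C-SH2/PTP interface
  (Arg111, Phe113, Glu250, Leu254, Gln257, Pro491, Gln495);
* ``allo_site_2`` — the N-SH2/PTP interface pocket flanked by Glu83 and
  Arg265, capped by a flexible loop (His85-Asp90, Gln92-Val95);
* ``allo_closite`` — the junction pocket whose members span all three
  domains, with the Arg23/Glu176 gatekeeper pair at its rim.

Pocket integrity is tracked through CA distances of cross-domain residue
pairs against a reference (closed) state: rising distances mean disruption,
converging distances mean a formed pocket.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import distance_series, superpose
from .structio import DomainMap, Structure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PocketDefinition",
    "PocketStateProfile",
    "ClusterResult",
    "builtin_pockets",
    "integrity_profile",
    "loop_state",
    "cluster_frames",
    "GATEKEEPER_PAIR",
    "ALLO_SITE_2_LOOP",
]

#: Gatekeeper residues whose salt bridge caps the junction pocket on binding.
GATEKEEPER_PAIR = (23, 176)  # Arg23 (N-SH2), Glu176 (C-SH2)

#: Disordered loop adjacent to allo-site-2 that toggles between an 'in'
#: (capping) and 'out' (open) conformation.
ALLO_SITE_2_LOOP = tuple(range(85, 91)) + tuple(range(92, 96))


@dataclass
class PocketDefinition:
    """A named pocket: member residues plus cross-domain integrity pairs."""

    name: str
    members: list[tuple[str | None, int, str]]  # (chain, res_seq, domain tag)
    key_pairs: list[tuple[int, int]]  # author-numbered residue pairs
    reference_state: Structure | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pocket {self.name!r}: members must be non-empty")
        tags = {r: d for _, r, d in self.members}
        for a, b in self.key_pairs:
            if tags.get(a) == tags.get(b) and tags.get(a) is not None:
                raise ValueError(
                    f"pocket {self.name!r}: key pair ({a},{b}) does not span "
                    "two domains"
                )

    @property
    def residues(self) -> list[int]:
        return sorted({r for _, r, _ in self.members})

    def validate_against(self, dm: DomainMap) -> list[str]:
        """Check member domain tags against the interval map.

        Returns human-readable warnings for members whose residue number
        falls outside their tagged domain (interface residues sit on the
        inter-domain linkers, so this is reported, not raised).
        """
        notes = []
        for _, res, tag in self.members:
            found = dm.domain_of(res)
            if found is None:
                notes.append(
                    f"{self.name}: residue {res} (tagged {tag}) lies on a "
                    "linker outside all domain intervals"
                )
            elif found != tag:
                notes.append(
                    f"{self.name}: residue {res} tagged {tag} but falls in "
                    f"interval of {found}"
                )
        for note in notes:
            logger.warning(note)
        return notes

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "members": [[c, r, d] for c, r, d in self.members],
                "key_pairs": [list(p) for p in self.key_pairs],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PocketDefinition":
        obj = json.loads(text)
        return cls(
            name=obj["name"],
            members=[tuple(m) for m in obj["members"]],
            key_pairs=[tuple(p) for p in obj["key_pairs"]],
        )


def _members(domain: str, pairs: list[tuple[int, str]]):
    return [(None, r, domain) for r, _ in pairs]


def builtin_pockets() -> dict[str, PocketDefinition]:
    """The three SHP2 pockets with their literature residue sets.

    Domain tags follow the source assignments; the junction pocket's default
    integrity pairs are six representative cross-domain pairs (one per
    domain pair per terminus of the member list) — the full pair matrix can
    be built from ``members`` if needed.
    """
    allo_site_1 = PocketDefinition(
        name="allo_site_1",
        members=[
            (None, 111, "C-SH2"),   # Arg111
            (None, 113, "PTP"),     # Phe113 (source's assignment; sits on the
                                    # C-SH2 interval — see validate_against)
            (None, 250, "PTP"),     # Glu250
            (None, 254, "PTP"),     # Leu254
            (None, 257, "PTP"),     # Gln257
            (None, 491, "PTP"),     # Pro491
            (None, 495, "PTP"),     # Gln495
        ],
        key_pairs=[(111, 113)],
    )
    allo_site_2 = PocketDefinition(
        name="allo_site_2",
        members=[(None, 83, "N-SH2"), (None, 265, "PTP")],
        key_pairs=[(83, 265)],
    )
    nsh2 = [8, 10, 11, 12, 14, 15, 18, 19, 22, 23, 103, 104, 105, 106]
    csh2 = [144, 147, 174, 175, 176, 177, 178, 179, 188, 189]
    ptp = [239, 240, 241, 242]
    allo_closite = PocketDefinition(
        name="allo_closite",
        members=(
            [(None, r, "N-SH2") for r in nsh2]
            + [(None, r, "C-SH2") for r in csh2]
            + [(None, r, "PTP") for r in ptp]
        ),
        key_pairs=[
            (8, 144), (106, 189),    # N-SH2 <-> C-SH2
            (8, 239), (106, 242),    # N-SH2 <-> PTP
            (144, 239), (189, 242),  # C-SH2 <-> PTP
        ],
    )
    return {
        "allo_site_1": allo_site_1,
        "allo_site_2": allo_site_2,
        "allo_closite": allo_closite,
    }


# ---------------------------------------------------------------------------
# Integrity profile


@dataclass
class PocketStateProfile:
    """Per-frame pocket integrity relative to a reference state.

    ``deviation`` is the mean absolute difference of the key-pair CA
    distances from their reference values; frames at or below ``threshold``
    are labelled formed, the rest disrupted.
    """

    pocket: str
    deviation: np.ndarray  # Angstrom per frame
    labels: np.ndarray  # "formed" | "disrupted"
    threshold: float
    pair_distances: np.ndarray = field(repr=False, default=None)  # (n_frames, n_pairs)

    @property
    def fraction_formed(self) -> float:
        return float(np.mean(self.labels == "formed"))

    @property
    def fraction_disrupted(self) -> float:
        return float(np.mean(self.labels == "disrupted"))

    def first_disrupted_frame(self) -> int | None:
        """1-based index of the first disrupted frame, or None."""
        idx = np.flatnonzero(self.labels == "disrupted")
        return int(idx[0]) + 1 if len(idx) else None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(1, len(self.deviation) + 1),
                "deviation": self.deviation,
                "label": self.labels,
            }
        )


def integrity_profile(
    traj: Trajectory,
    pocket: PocketDefinition,
    ref: Structure,
    threshold: float = 2.0,
) -> PocketStateProfile:
    """Track pocket integrity via cross-domain CA distances against ``ref``.

    The reference must be supplied explicitly (typically the closed crystal
    structure or the dominant-cluster representative).  Distances are
    internal coordinates, so the profile is invariant under rigid-body
    motion of whole frames.
    """
    ref_index = {
        (r, "CA"): None for _, r, _ in pocket.members
    }  # existence check below
    for a, b in pocket.key_pairs:
        for res in (a, b):
            if not np.any((traj.topology.res_seq == res) & (traj.topology.name == "CA")):
                raise KeyError(f"residue {res} (CA) missing from trajectory topology")
            if not np.any((ref.res_seq == res) & (ref.name == "CA")):
                raise KeyError(f"residue {res} (CA) missing from reference structure")

    n_frames = traj.n_frames
    pair_d = np.empty((n_frames, len(pocket.key_pairs)))
    ref_d = np.empty(len(pocket.key_pairs))
    ref_traj = Trajectory(topology=ref, frames=ref.coords[None, :, :])
    for j, (a, b) in enumerate(pocket.key_pairs):
        pair_d[:, j] = distance_series(traj, a, b).values
        ref_d[j] = distance_series(ref_traj, a, b).values[0]
    deviation = np.mean(np.abs(pair_d - ref_d), axis=1)
    labels = np.where(deviation <= threshold, "formed", "disrupted")
    return PocketStateProfile(
        pocket=pocket.name,
        deviation=deviation,
        labels=labels,
        threshold=threshold,
        pair_distances=pair_d,
    )


# ---------------------------------------------------------------------------
# Loop in/out state


def loop_state(
    traj: Trajectory,
    loop: list[int] | tuple[int, ...] = ALLO_SITE_2_LOOP,
    pocket: PocketDefinition | None = None,
    cutoff: float = 8.0,
) -> np.ndarray:
    """Per-frame {'in', 'out'} call for the capping loop.

    'in' iff the loop CA centroid lies within ``cutoff`` (A) of the pocket
    member CA centroid.
    """
    if pocket is None:
        pocket = builtin_pockets()["allo_site_2"]
    top = traj.topology
    loop_idx = np.flatnonzero(np.isin(top.res_seq, list(loop)) & (top.name == "CA"))
    if len(loop_idx) == 0:
        raise KeyError(f"loop residues {list(loop)} absent from topology")
    pocket_idx = np.flatnonzero(
        np.isin(top.res_seq, pocket.residues) & (top.name == "CA")
    )
    if len(pocket_idx) == 0:
        raise KeyError(f"pocket {pocket.name!r} residues absent from topology")
    loop_c = traj.frames[:, loop_idx, :].mean(axis=1)
    pocket_c = traj.frames[:, pocket_idx, :].mean(axis=1)
    d = np.linalg.norm(loop_c - pocket_c, axis=1)
    return np.where(d <= cutoff, "in", "out")


# ---------------------------------------------------------------------------
# Conformational clustering


@dataclass
class ClusterResult:
    """k-means clustering of superposed frames.

    ``representative[c]`` is the member frame closest to cluster c's mean;
    ``dominant`` is the representative of the most-populated cluster — the
    receptor-extraction convention for docking.
    Frame indices are 0-based.
    """

    k: int
    assignment: np.ndarray  # frame -> cluster id
    populations: np.ndarray  # per cluster
    representative: np.ndarray  # per cluster, frame index
    dominant: int  # frame index

    def __post_init__(self):
        if int(self.populations.sum()) != len(self.assignment):
            raise ValueError("populations must sum to frame count")


def cluster_frames(
    traj: Trajectory, k: int = 10, seed: int = 0
) -> ClusterResult:
    """Cluster frames by heavy-to-CB RMSD geometry, k-means, fixed seed.

    Frames are first globally superposed onto frame 1 using the
    backbone-plus-CB heavy-atom set, then k-means runs on the flattened
    coordinates of that set (Euclidean distance on superposed coordinates
    is a monotone proxy for RMSD at fixed atom count).  Empty clusters are
    relocated internally by the k-means implementation; the result is
    reproducible for a fixed seed.
    """
    from sklearn.cluster import KMeans

    if traj.n_frames < k:
        raise ValueError(
            f"{traj.n_frames} frames < k={k}; choose a smaller cluster count"
        )
    sel_idx = np.flatnonzero(
        np.isin(traj.topology.name, sorted({"N", "CA", "C", "O", "CB", "OXT"}))
        & ~np.isin(traj.topology.element, ["H", "D"])
    )
    ref = traj.frames[0, sel_idx, :]
    fitted = np.empty((traj.n_frames, len(sel_idx), 3))
    fitted[0] = ref
    for i in range(1, traj.n_frames):
        sp = superpose(traj.frames[i, sel_idx, :], ref)
        fitted[i] = sp.apply(traj.frames[i, sel_idx, :])
    X = fitted.reshape(traj.n_frames, -1)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assignment = km.fit_predict(X)
    populations = np.bincount(assignment, minlength=k)
    representative = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(assignment == c)
        if len(members) == 0:  # cannot happen with sklearn's relocation
            representative[c] = -1
            continue
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        representative[c] = members[int(np.argmin(d))]
    dominant = int(representative[int(np.argmax(populations))])
    return ClusterResult(
        k=k,
        assignment=assignment,
        populations=populations,
        representative=representative,
        dominant=dominant,
    )
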