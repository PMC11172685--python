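"""Superposition, RMSD, distance series, interdomain rotation and contacts.

This is the metric core of the package: least-squares rigid-body fitting
(Kabsch, reflection excluded), paired RMSD, per-frame residue distance
series, the rotation angle between domain orientations in two structures,
salt-bridge geometry for the pocket gatekeeper pair, and a geometric
protein-ligand contact profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import DomainMap, Structure, Trajectory, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "Superposition",
    "DistanceSeries",
    "Contact",
    "ContactProfile",
    "AtomSpec",
    "superpose",
    "rmsd_paired",
    "distance_series",
    "domain_rotation_angle",
    "gatekeeper_series",
    "contact_profile",
]


class DegenerateInputError(ValueError):
    """Raised when a point set is too small or rank-deficient to fit."""


@dataclass
class Superposition:
    """A proper rigid-body transform minimizing weighted squared deviations.

    ``apply(x)`` maps mobile coordinates onto the reference frame:
    ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd_after: float  # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        return rotation_angle_deg(self.rotation)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, in [0, 180] degrees."""
    cos_theta = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))


def rotation_axis(R: np.ndarray) -> np.ndarray:
    """Unit rotation axis (auxiliary output; arbitrary sign at 0/180 deg)."""
    w, v = np.linalg.eig(R)
    i = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, i])
    return axis / np.linalg.norm(axis)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-squares fit of ``mobile`` onto ``reference`` (Kabsch, SVD).

    Reflections are excluded: the returned rotation always has det +1.
    Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mu_m = (w[:, None] * mobile).sum(0) / wsum
    mu_r = (w[:, None] * reference).sum(0) / wsum
    X = mobile - mu_m
    Y = reference - mu_r
    # collinearity check: centred point cloud must span a plane
    if np.linalg.matrix_rank(X, tol=1e-9) < 2 or np.linalg.matrix_rank(Y, tol=1e-9) < 2:
        raise DegenerateInputError("point set is collinear or rank-deficient")
    H = (w[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt((w * ((fitted - reference) ** 2).sum(1)).sum() / wsum))
    return Superposition(rotation=R, translation=t, rmsd_after=rmsd)


def rmsd_paired(A: np.ndarray, B: np.ndarray, fit: bool = False) -> float:
    """RMSD between position-corresponded coordinate sets.

    With ``fit=True`` A is first superposed onto B; otherwise raw paired RMSD.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate count mismatch: {A.shape} vs {B.shape}")
    if fit:
        return superpose(A, B).rmsd_after
    return float(np.sqrt(((A - B) ** 2).sum(1).mean()))


# ---------------------------------------------------------------------------
# Distance series


@dataclass(frozen=True)
class AtomSpec:
    """Addresses exactly one atom: residue (author numbering) + atom name."""

    res_seq: int
    atom_name: str = "CA"
    chain_id: str | None = None

    def resolve(self, s: Structure) -> int:
        """Index of the single matching atom; ambiguity and absence raise."""
        mask = (s.res_seq == self.res_seq) & (s.name == self.atom_name)
        if self.chain_id is not None:
            mask &= s.chain_id == self.chain_id
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"no atom matches {self}")
        if len(idx) > 1:
            matches = [
                f"{s.chain_id[i]}/{s.res_name[i]}{s.res_seq[i]}/{s.name[i]}"
                f"(alt {s.alt_loc[i] or '-'})"
                for i in idx
            ]
            raise ValueError(f"ambiguous spec {self}: matches {matches}")
        return int(idx[0])


def _as_spec(spec) -> AtomSpec:
    if isinstance(spec, AtomSpec):
        return spec
    if isinstance(spec, int):
        return AtomSpec(res_seq=spec)
    if isinstance(spec, tuple):
        return AtomSpec(*spec) if not isinstance(spec[0], str) else AtomSpec(
            res_seq=spec[1], chain_id=spec[0]
        )
    raise TypeError(f"cannot interpret atom spec {spec!r}")


@dataclass
class DistanceSeries:
    """Per-frame Euclidean distance between two atoms (no fitting)."""

    pair_label: str
    values: np.ndarray  # Angstrom, one per frame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"frame": np.arange(1, len(self) + 1), "value": self.values,
             "label": self.pair_label}
        )


def distance_series(traj: Trajectory, a, b) -> DistanceSeries:
    """CA-CA (or named-atom) distance per frame, in the raw trajectory frame."""
    sa, sb = _as_spec(a), _as_spec(b)
    ia = sa.resolve(traj.topology)
    ib = sb.resolve(traj.topology)
    d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    top = traj.topology
    label = (
        f"{top.res_name[ia]}{top.res_seq[ia]}:{top.name[ia]}"
        f"-{top.res_name[ib]}{top.res_seq[ib]}:{top.name[ib]}"
    )
    return DistanceSeries(pair_label=label, values=d)


# ---------------------------------------------------------------------------
# Interdomain rotation


def _shared_ca(sA: Structure, sB: Structure, residues: Sequence[int]):
    """CA coordinate pairs for residues shared by both structures.

    Matching key is (chain, res_seq, res_name); a residue whose name differs
    between the structures at the same number is excluded and logged.
    """
    caA = select_atoms(sA, res_range=list(residues), atom_class="CA")
    caB = select_atoms(sB, res_range=list(residues), atom_class="CA")
    keyA = {
        (str(c), int(r), str(n)): i
        for i, (c, r, n) in enumerate(zip(caA.chain_id, caA.res_seq, caA.res_name))
    }
    coordsA, coordsB = [], []
    seenB = set()
    for i, (c, r, n) in enumerate(zip(caB.chain_id, caB.res_seq, caB.res_name)):
        key = (str(c), int(r), str(n))
        if key in keyA:
            coordsA.append(caA.coords[keyA[key]])
            coordsB.append(caB.coords[i])
            seenB.add((str(c), int(r)))
    mismatched = {
        (c, r) for (c, r, n) in keyA
        if (c, r) not in seenB and any(int(rB) == r and str(cB) == c
                                       for cB, rB in zip(caB.chain_id, caB.res_seq))
    }
    if mismatched:
        logger.warning("excluded residues with mismatched names: %s", sorted(mismatched))
    return np.asarray(coordsA), np.asarray(coordsB)


def domain_rotation_angle(
    sA: Structure,
    sB: Structure,
    dm: DomainMap,
    anchor: str,
    mobile: str,
    return_axis: bool = False,
):
    """Rotation (degrees) of the ``mobile`` domain between two structures.

    Both structures are first superposed on the shared CA atoms of the
    ``anchor`` domain; the rigid rotation mapping the mobile domain of sA
    onto sB is then extracted and its angle returned in [0, 180].  This is
    the quantity behind the ~120 deg C-SH2 swing between the SHP2 closed
    and open states.
    """
    ancA, ancB = _shared_ca(sA, sB, dm.residues(anchor))
    mobA, mobB = _shared_ca(sA, sB, dm.residues(mobile))
    if len(ancA) < 3:
        raise DegenerateInputError(
            f"fewer than 3 shared CA atoms in anchor domain {anchor!r}"
        )
    if len(mobA) < 3:
        raise DegenerateInputError(
            f"fewer than 3 shared CA atoms in mobile domain {mobile!r}"
        )
    anchor_fit = superpose(ancA, ancB)
    mobA_in_B = anchor_fit.apply(mobA)
    mobile_fit = superpose(mobA_in_B, mobB)
    angle = rotation_angle_deg(mobile_fit.rotation)
    if return_axis:
        return angle, rotation_axis(mobile_fit.rotation)
    return angle


# ---------------------------------------------------------------------------
# Gatekeeper salt bridge

#: Side-chain nitrogen atoms that carry (or share) a positive charge.
_CATION_N = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
#: Side-chain carboxylate oxygens.
_ANION_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


def _charged_atom_indices(top: Structure, res_seq: int, chain: str | None):
    mask = top.res_seq == res_seq
    if chain is not None:
        mask &= top.chain_id == chain
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise KeyError(f"residue {res_seq} not found")
    res_name = str(top.res_name[idx[0]])
    n_names = _CATION_N.get(res_name, set())
    o_names = _ANION_O.get(res_name, set())
    n_idx = [int(i) for i in idx if str(top.name[i]) in n_names]
    o_idx = [int(i) for i in idx if str(top.name[i]) in o_names]
    ca = [int(i) for i in idx if str(top.name[i]) == "CA"]
    if not ca:
        raise KeyError(f"residue {res_name}{res_seq} has no CA atom")
    return res_name, ca[0], n_idx, o_idx


def gatekeeper_series(
    traj: Trajectory,
    resA: int | tuple[str, int],
    resB: int | tuple[str, int],
) -> tuple[DistanceSeries, DistanceSeries]:
    """CA-CA and minimum charged-N to carboxylate-O distance per frame.

    Built for salt-bridge formation between a basic and an acidic residue
    (the Arg23/Glu176 gatekeeper pair capping the three-domain junction
    pocket); raises if neither residue ordering provides an N/O pairing.
    """
    chA, rA = resA if isinstance(resA, tuple) else (None, resA)
    chB, rB = resB if isinstance(resB, tuple) else (None, resB)
    nameA, caA, nA, oA = _charged_atom_indices(traj.topology, rA, chA)
    nameB, caB, nB, oB = _charged_atom_indices(traj.topology, rB, chB)
    if nA and oB:
        n_idx, o_idx = nA, oB
    elif nB and oA:
        n_idx, o_idx = nB, oA
    else:
        raise ValueError(
            f"residues {nameA}{rA} / {nameB}{rB} lack complementary charged "
            "side-chain atoms (need a basic N / acidic O pair)"
        )
    ca_d = np.linalg.norm(traj.frames[:, caA, :] - traj.frames[:, caB, :], axis=1)
    pair_d = np.min(
        np.linalg.norm(
            traj.frames[:, n_idx, None, :] - traj.frames[:, None, o_idx, :], axis=-1
        ),
        axis=(1, 2),
    )
    label = f"{nameA}{rA}-{nameB}{rB}"
    return (
        DistanceSeries(pair_label=f"{label}:CA-CA", values=ca_d),
        DistanceSeries(pair_label=f"{label}:minNO", values=pair_d),
    )


# ---------------------------------------------------------------------------
# Contact profile


@dataclass(frozen=True)
class Contact:
    ligand_atom: int  # index into the ligand structure
    res_name: str
    res_seq: int
    chain_id: str
    type: str  # hbond | hydrophobic | salt_bridge | cation_pi
    distance: float  # Angstrom


@dataclass
class ContactProfile:
    contacts: list[Contact] = field(default_factory=list)

    def count(self, type: str | None = None) -> int:
        if type is None:
            return len(self.contacts)
        return sum(1 for c in self.contacts if c.type == type)

    def residues(self) -> list[tuple[str, int]]:
        return sorted({(c.res_name, c.res_seq) for c in self.contacts})

    def to_json(self) -> str:
        import json

        return json.dumps([c.__dict__ for c in self.contacts])


#: Aromatic side-chain ring atom names for protein residues.
_AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


def _covalent_partners(s: Structure, i: int, cutoff: float = 1.8) -> np.ndarray:
    d = np.linalg.norm(s.coords - s.coords[i], axis=1)
    mask = (d > 0) & (d <= cutoff)
    return np.flatnonzero(mask)


def _is_apolar_carbon(s: Structure, i: int) -> bool:
    if s.element[i] != "C":
        return False
    partners = _covalent_partners(s, i)
    return not any(s.element[j] in ("N", "O") for j in partners)


def contact_profile(
    receptor: Structure,
    ligand: Structure,
    ligand_charges: dict[int, int] | None = None,
    ligand_rings: Sequence[Sequence[int]] | None = None,
    hbond_cutoff: float = 3.5,
    hbond_angle_min: float = 120.0,
    hydrophobic_cutoff: float = 4.5,
    salt_bridge_cutoff: float = 3.5,
    cation_pi_cutoff: float = 6.0,
    cation_pi_angle_max: float = 45.0,
) -> ContactProfile:
    """Geometric protein-ligand interaction profile.

    Criteria: hydrogen bond = donor/acceptor N,O heavy-atom pair <= 3.5 A
    (D-H...A angle >= 120 deg enforced when an explicit H rides the donor);
    hydrophobic = apolar C...C <= 4.5 A; salt bridge = oppositely charged
    N...O <= 3.5 A; cation-pi = cation <= 6.0 A from an aromatic ring
    centroid and within 45 deg of the ring normal.

    Ligand formal charges and aromatic rings cannot be inferred from bare
    coordinates, so they are supplied as ``ligand_charges`` (atom index ->
    formal charge) and ``ligand_rings`` (tuples of ring atom indices); both
    default to empty.
    """
    if ligand.n_atoms == 0:
        raise ValueError("ligand has no atoms")
    ligand_charges = ligand_charges or {}
    ligand_rings = ligand_rings or []
    contacts: list[Contact] = []

    def _res(i: int) -> tuple[str, int, str]:
        return str(receptor.res_name[i]), int(receptor.res_seq[i]), str(receptor.chain_id[i])

    # hydrogen bonds: polar N/O pairs across the interface
    rec_polar = np.flatnonzero(np.isin(receptor.element, ["N", "O"]))
    lig_polar = np.flatnonzero(np.isin(ligand.element, ["N", "O"]))
    for li in lig_polar:
        for ri in rec_polar:
            d = float(np.linalg.norm(ligand.coords[li] - receptor.coords[ri]))
            if d > hbond_cutoff:
                continue
            if not _hbond_angle_ok(
                receptor, ligand, ri, int(li), hbond_angle_min
            ):
                continue
            rn, rs, ch = _res(ri)
            contacts.append(Contact(int(li), rn, rs, ch, "hbond", round(d, 3)))

    # hydrophobic: apolar carbon pairs
    lig_apolar = [i for i in range(ligand.n_atoms) if _is_apolar_carbon(ligand, i)]
    rec_apolar = [i for i in range(receptor.n_atoms) if _is_apolar_carbon(receptor, i)]
    for li in lig_apolar:
        for ri in rec_apolar:
            d = float(np.linalg.norm(ligand.coords[li] - receptor.coords[ri]))
            if d <= hydrophobic_cutoff:
                rn, rs, ch = _res(ri)
                contacts.append(Contact(li, rn, rs, ch, "hydrophobic", round(d, 3)))

    # salt bridges: opposite formal charges, N-O distance
    lig_cations = [i for i, q in ligand_charges.items() if q > 0]
    lig_anions = [i for i, q in ligand_charges.items() if q < 0]
    rec_cation_n = [
        i for i in range(receptor.n_atoms)
        if str(receptor.name[i]) in _CATION_N.get(str(receptor.res_name[i]), set())
    ]
    rec_anion_o = [
        i for i in range(receptor.n_atoms)
        if str(receptor.name[i]) in _ANION_O.get(str(receptor.res_name[i]), set())
    ]
    for li, rec_idx in ((l, rec_anion_o) for l in lig_cations):
        for ri in rec_idx:
            d = float(np.linalg.norm(ligand.coords[li] - receptor.coords[ri]))
            if d <= salt_bridge_cutoff:
                rn, rs, ch = _res(ri)
                contacts.append(Contact(li, rn, rs, ch, "salt_bridge", round(d, 3)))
    for li, rec_idx in ((l, rec_cation_n) for l in lig_anions):
        for ri in rec_idx:
            d = float(np.linalg.norm(ligand.coords[li] - receptor.coords[ri]))
            if d <= salt_bridge_cutoff:
                rn, rs, ch = _res(ri)
                contacts.append(Contact(li, rn, rs, ch, "salt_bridge", round(d, 3)))

    # cation-pi: ligand cation vs protein aromatic ring, and the reverse
    for li in lig_cations:
        for ring_atoms, (rn, rs, ch) in _protein_rings(receptor):
            hit, d = _cation_pi_ok(
                ligand.coords[li], receptor.coords[ring_atoms],
                cation_pi_cutoff, cation_pi_angle_max,
            )
            if hit:
                contacts.append(Contact(li, rn, rs, ch, "cation_pi", round(d, 3)))
    for ring in ligand_rings:
        ring = list(ring)
        for ri in rec_cation_n:
            hit, d = _cation_pi_ok(
                receptor.coords[ri], ligand.coords[ring],
                cation_pi_cutoff, cation_pi_angle_max,
            )
            if hit:
                rn, rs, ch = _res(ri)
                contacts.append(Contact(ring[0], rn, rs, ch, "cation_pi", round(d, 3)))

    return ContactProfile(contacts=contacts)


def _hbond_angle_ok(
    receptor: Structure, ligand: Structure, ri: int, li: int, angle_min: float
) -> bool:
    """Check D-H...A angle for every explicit H riding either polar atom."""
    for donor_s, donor_i, acc_xyz in (
        (ligand, li, receptor.coords[ri]),
        (receptor, ri, ligand.coords[li]),
    ):
        hydrogens = [
            j for j in _covalent_partners(donor_s, donor_i, cutoff=1.3)
            if donor_s.element[j] in ("H", "D")
        ]
        for h in hydrogens:
            v1 = donor_s.coords[donor_i] - donor_s.coords[h]
            v2 = acc_xyz - donor_s.coords[h]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle >= angle_min:
                return True
        if hydrogens:
            return False  # explicit H present but geometry fails
    return True  # no explicit hydrogens: distance criterion alone


def _protein_rings(receptor: Structure):
    for (chain, res_seq), span in receptor.residue_index.items():
        res_name = str(receptor.res_name[span.start])
        names = _AROMATIC_RINGS.get(res_name)
        if names is None:
            continue
        idx = [
            i for i in range(span.start, span.stop)
            if str(receptor.name[i]) in names
        ]
        if len(idx) >= 5:
            yield idx, (res_name, int(res_seq), str(chain))


def _cation_pi_ok(
    cation_xyz: np.ndarray,
    ring_xyz: np.ndarray,
    cutoff: float,
    angle_max: float,
) -> tuple[bool, float]:
    centroid = ring_xyz.mean(0)
    d = float(np.linalg.norm(cation_xyz - centroid))
    if d > cutoff:
        return False, d
    # ring normal via SVD of centred ring coordinates
    _, _, Vt = np.linalg.svd(ring_xyz - centroid)
    normal = Vt[2]
    v = cation_xyz - centroid
    cosang = abs(v @ normal) / np.linalg.norm(v)
    off_normal = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    return off_normal <= angle_max, d
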