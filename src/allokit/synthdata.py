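"""Synthetic inputs with planted ground truth for every pipeline stage.

These generators are statistical stand-ins, not physics: a bead-style SHP2
receptor whose residue numbering matches the literature pocket members, a
Gaussian-fluctuation trajectory with riggable distance-shift events (pocket
disruption, gatekeeper salt-bridge closure, loop in/out), paired docking
score tables with a tunable inter-receptor rank correlation and planted
strong binders, ligand-RMSD traces of the three stability classes, and a
toy SDF library with controlled fractions violating each pre-filter rule.

Every generator is a pure function of its spec: one ``numpy`` RNG is
created per call from ``spec.seed`` and no global state is touched, so the
same spec reproduces identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stability import LigandRmsdSeries
from .structio import DomainMap, ScoreTable, Structure, Trajectory

__all__ = [
    "SyntheticSpec",
    "Event",
    "gen_toy_receptor",
    "gen_trajectory",
    "gen_score_tables",
    "gen_ligand_traces",
    "gen_compound_library",
    "salt_bridge_closure_event",
    "disruption_event",
    "loop_out_event",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the screening/triage regime the pipeline is built for:
    2000-compound score tables with a 0.5 kcal/mol affinity noise floor and
    30 planted binders 3 kcal/mol below it; 100-frame trajectories (one
    frame per ns of a Tier-III production run) with 0.3 A per-coordinate
    thermal fluctuation around the reference.
    """

    seed: int = 0
    # trajectories
    n_frames: int = 100
    fluctuation_sigma: float = 0.3  # A per coordinate
    planted_events: tuple["Event", ...] = ()
    # score tables
    n_compounds: int = 2000
    rank_correlation: float = 0.5  # rho in [-1, 1]
    planted_hits: tuple[int, float] = (30, 3.0)  # (count m, gap Delta kcal/mol)
    noise_sigma: float = 0.5  # kcal/mol marginal spread
    baseline_affinity: float = -7.0  # kcal/mol
    # compound library
    n_library: int = 100
    filter_violation_fractions: tuple[float, float, float] = (0.1, 0.1, 0.1)
    # toy receptor
    domain_intervals: dict | None = None

    def __post_init__(self):
        if min(self.n_frames, self.n_compounds, self.n_library) < 0:
            raise ValueError("counts must be non-negative")
        if not -1.0 <= self.rank_correlation <= 1.0:
            raise ValueError("rank_correlation must lie in [-1, 1]")
        if self.planted_hits[0] > self.n_compounds:
            raise ValueError("cannot plant more hits than compounds")
        if sum(self.filter_violation_fractions) > 1.0 + 1e-12:
            raise ValueError("filter violation fractions must sum to <= 1")


@dataclass(frozen=True)
class Event:
    """Rigid offset applied to named atoms from a frame onward (1-based).

    Frames with index >= ``start_frame`` have ``translation`` added to every
    atom of ``residues`` (optionally restricted to ``atom_names``).
    """

    start_frame: int
    residues: tuple[int, ...]
    translation: tuple[float, float, float]
    atom_names: tuple[str, ...] | None = None


# ---------------------------------------------------------------------------
# Toy receptor

#: Residue names for every literature-cited residue the pockets, loop and
#: gatekeepers reference (2SHP author numbering).
_NAMED_RESIDUES: dict[int, str] = {
    8: "HIS", 10: "ASN", 11: "ILE", 12: "THR", 14: "VAL", 15: "GLU",
    18: "ASN", 19: "LEU", 22: "THR", 23: "ARG",
    83: "GLU", 85: "HIS", 86: "ALA", 87: "ALA", 88: "ALA", 89: "ALA",
    90: "ASP", 92: "GLN", 93: "ALA", 94: "ALA", 95: "VAL",
    103: "ASN", 104: "CYS", 105: "ALA", 106: "ASP", 111: "ARG", 113: "PHE",
    144: "PRO", 147: "PHE", 174: "CYS", 175: "GLN", 176: "GLU", 177: "LEU",
    178: "GLU", 179: "TYR", 188: "ASP", 189: "SER",
    221: "ALA", 238: "GLU", 239: "THR", 240: "THR", 241: "ASP", 242: "LYS",
    250: "GLU", 254: "LEU", 257: "GLN", 265: "ARG", 491: "PRO", 495: "GLN",
    524: "ALA",
}

_FILLER_RESIDUES = (30, 40, 50, 60, 70, 120, 130, 155, 200, 280, 300, 350, 400, 450)

_DOMAIN_CENTERS = {
    "N-SH2": np.array([0.0, 0.0, 0.0]),
    "C-SH2": np.array([40.0, 0.0, 0.0]),
    "PTP": np.array([20.0, 35.0, 0.0]),
}

#: Charged side-chain pseudo-atoms added per residue type.
_SIDE_CHAIN_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Hand-placed CA positions: the Arg23/Glu176 gatekeepers sit on the facing
#: edges of their domains ~17 A apart (the pre-binding separation), and the
#: capping loop starts in its 'in' state near the site-2 member centroid.
_SPECIAL_CA = {
    23: np.array([11.5, 0.0, 0.0]),
    176: np.array([28.5, 0.0, 0.0]),
    83: np.array([8.0, 10.0, 0.0]),
    265: np.array([12.0, 24.0, 0.0]),
}
_LOOP_CENTER = np.array([10.0, 14.0, 0.0])
_LOOP_RESIDUES = (85, 86, 87, 88, 89, 90, 92, 93, 94, 95)


def _bucket(res_seq: int) -> str:
    if res_seq < 112:
        return "N-SH2"
    if res_seq < 221:
        return "C-SH2"
    return "PTP"


def gen_toy_receptor(spec: SyntheticSpec) -> Structure:
    """A three-pseudo-domain bead receptor resolving every builtin pocket.

    Each residue carries CA and CB beads (plus charged side-chain beads for
    Arg/Lys/Asp/Glu) laid out on jittered grids around well-separated
    domain centers; residue numbering matches the literature member lists
    so the builtin pockets, loop and gatekeepers all resolve.
    """
    if spec.domain_intervals is not None:
        DomainMap(spec.domain_intervals)  # raises on overlap
    rng = np.random.default_rng(spec.seed)
    residues = sorted(set(_NAMED_RESIDUES) | set(_FILLER_RESIDUES))
    by_domain: dict[str, list[int]] = {"N-SH2": [], "C-SH2": [], "PTP": []}
    for r in residues:
        by_domain[_bucket(r)].append(r)

    ca_pos: dict[int, np.ndarray] = {}
    for domain, members in by_domain.items():
        center = _DOMAIN_CENTERS[domain]
        side = math.ceil(len(members) ** (1 / 3))
        for i, r in enumerate(members):
            ix, iy, iz = i % side, (i // side) % side, i // (side * side)
            grid = (np.array([ix, iy, iz], dtype=float) - (side - 1) / 2) * 5.0
            ca_pos[r] = center + grid + rng.uniform(-0.4, 0.4, 3)
    for r, xyz in _SPECIAL_CA.items():
        ca_pos[r] = xyz.copy()
    for i, r in enumerate(_LOOP_RESIDUES):
        ang = 2 * np.pi * i / len(_LOOP_RESIDUES)
        ca_pos[r] = _LOOP_CENTER + 2.0 * np.array([np.cos(ang), np.sin(ang), 0.0])

    serial, names, elements, res_names, res_seqs, coords = [], [], [], [], [], []
    next_serial = 1

    def _add(res: int, res_name: str, atom: str, element: str, xyz: np.ndarray):
        nonlocal next_serial
        serial.append(next_serial)
        names.append(atom)
        elements.append(element)
        res_names.append(res_name)
        res_seqs.append(res)
        coords.append(xyz)
        next_serial += 1

    for r in residues:
        res_name = _NAMED_RESIDUES.get(r, "ALA")
        ca = ca_pos[r]
        _add(r, res_name, "CA", "C", ca)
        toward = _DOMAIN_CENTERS[_bucket(r)] - ca
        norm = np.linalg.norm(toward)
        u = toward / norm if norm > 1e-6 else np.array([0.0, 0.0, 1.0])
        _add(r, res_name, "CB", "C", ca + 1.53 * u)
        sc = _SIDE_CHAIN_ATOMS.get(res_name, ())
        # gatekeepers point their charged groups at each other
        if r == 23:
            u = np.array([1.0, 0.0, 0.0])
        elif r == 176:
            u = np.array([-1.0, 0.0, 0.0])
        for j, atom in enumerate(sc):
            elem = atom[0]  # N or O
            _add(r, res_name, atom, elem, ca + (2.8 + 0.3 * j) * u)

    n = len(serial)
    return Structure(
        serial=np.array(serial),
        name=np.array(names),
        element=np.array(elements),
        alt_loc=np.full(n, ""),
        res_name=np.array(res_names),
        chain_id=np.full(n, "A"),
        res_seq=np.array(res_seqs),
        coords=np.array(coords),
    )


# ---------------------------------------------------------------------------
# Trajectories


def gen_trajectory(base: Structure, spec: SyntheticSpec) -> Trajectory:
    """Gaussian fluctuations around ``base`` plus planted rigid-offset events."""
    rng = np.random.default_rng(spec.seed)
    frames = base.coords[None, :, :] + rng.normal(
        0.0, spec.fluctuation_sigma, size=(spec.n_frames, base.n_atoms, 3)
    )
    for ev in spec.planted_events:
        mask = np.isin(base.res_seq, list(ev.residues))
        if ev.atom_names is not None:
            mask &= np.isin(base.name, list(ev.atom_names))
        if not mask.any():
            raise KeyError(
                f"event references unknown atoms: residues {ev.residues}"
                + (f", atoms {ev.atom_names}" if ev.atom_names else "")
            )
        frames[ev.start_frame - 1:, mask, :] += np.asarray(ev.translation)
    return Trajectory(topology=base, frames=frames)


def disruption_event(
    start_frame: int,
    residues: tuple[int, ...] = (239, 240, 241, 242, 144, 147, 174, 175, 176,
                                 177, 178, 179, 188, 189),
    offset: tuple[float, float, float] = (8.0, 0.0, 0.0),
) -> Event:
    """Push one flank of the junction pocket away: CA distances jump by ~|offset|."""
    return Event(start_frame=start_frame, residues=residues, translation=offset)


def salt_bridge_closure_event(
    base: Structure,
    start_frame: int,
    res_cation: int = 23,
    res_anion: int = 176,
    target: float = 2.8,
) -> Event:
    """Move the acidic side chain onto the basic one to ``target`` A min N-O."""
    n_mask = (base.res_seq == res_cation) & np.isin(base.name, ["NE", "NH1", "NH2", "NZ"])
    o_mask = (base.res_seq == res_anion) & np.isin(base.name, ["OD1", "OD2", "OE1", "OE2"])
    if not n_mask.any() or not o_mask.any():
        raise KeyError(
            f"residues {res_cation}/{res_anion} lack charged side-chain beads"
        )
    n_xyz = base.coords[n_mask]
    o_xyz = base.coords[o_mask]
    d = np.linalg.norm(n_xyz[:, None, :] - o_xyz[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    vec = n_xyz[i] - o_xyz[j]
    dist = float(np.linalg.norm(vec))
    shift = vec / dist * (dist - target)
    sc = _SIDE_CHAIN_ATOMS.get(str(base.res_name[np.flatnonzero(o_mask)[0]]), ())
    return Event(
        start_frame=start_frame,
        residues=(res_anion,),
        translation=tuple(shift),
        atom_names=tuple(sc) or None,
    )


def loop_out_event(
    start_frame: int,
    offset: tuple[float, float, float] = (0.0, 12.0, 0.0),
) -> Event:
    """Swing the capping loop away from the site-2 member centroid."""
    return Event(start_frame=start_frame, residues=_LOOP_RESIDUES, translation=offset)


# ---------------------------------------------------------------------------
# Score tables


def gen_score_tables(
    spec: SyntheticSpec,
    receptor_a: str = "wtSHP2-b",
    receptor_b: str = "mtSHP2-b",
) -> tuple[ScoreTable, ScoreTable, dict]:
    """Paired docking score tables with planted binders and tuned correlation.

    Each compound has a shared latent affinity plus receptor-specific noise;
    variances are split so the inter-receptor Pearson correlation of
    affinities is ``rank_correlation`` while the marginal spread stays
    ``noise_sigma``.  The ``m`` planted hits get their shared affinity
    lowered by ``Delta``, so both receptors see them as strong binders.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    m, delta = spec.planted_hits
    rho = spec.rank_correlation
    ids = np.array([f"CMP-{i:05d}" for i in range(1, n + 1)])
    planted = rng.choice(ids, size=m, replace=False) if m else np.array([], dtype=ids.dtype)
    planted_mask = np.isin(ids, planted)

    sigma_shared = spec.noise_sigma * math.sqrt(abs(rho))
    sigma_noise = spec.noise_sigma * math.sqrt(1.0 - abs(rho))
    z = rng.normal(0.0, 1.0, n) * sigma_shared
    eps_a = rng.normal(0.0, 1.0, n) * sigma_noise
    eps_b = rng.normal(0.0, 1.0, n) * sigma_noise
    base = np.full(n, spec.baseline_affinity)
    base[planted_mask] -= delta
    aff_a = base + z + eps_a
    aff_b = base + (np.sign(rho) if rho else 1.0) * z + eps_b

    def _table(receptor: str, aff: np.ndarray) -> ScoreTable:
        return ScoreTable(
            pd.DataFrame(
                {
                    "compound_id": ids,
                    "receptor_id": receptor,
                    "affinity": np.round(aff, 4),
                    "pose_rank": 1,
                }
            )
        )

    truth = {
        "planted_ids": sorted(planted.tolist()),
        "delta": delta,
        "rho": rho,
        "noise_sigma": spec.noise_sigma,
        "baseline_affinity": spec.baseline_affinity,
        "n_compounds": n,
    }
    return _table(receptor_a, aff_a), _table(receptor_b, aff_b), truth


# ---------------------------------------------------------------------------
# Ligand RMSD traces

#: Target bands for the fraction of frames below the 3 A criterion; chosen
#: to sit strictly inside the classifier's default 0.90/0.50 boundaries.
_CLASS_BANDS = {
    "highly_stable": (0.95, 1.0),
    "partially_stable": (0.60, 0.85),
    "unstable": (0.05, 0.40),
}


def gen_ligand_traces(
    klass: str,
    spec: SyntheticSpec,
    compound_id: str = "ligand",
    receptor_id: str = "receptor",
    threshold: float = 3.0,
) -> tuple[LigandRmsdSeries, dict]:
    """One RMSD trace of the requested stability class, with exact truth.

    Frames below threshold sample U(0.5, 2.5) A, frames above U(3.5, 6.5) A;
    the first frame is pinned at 0 (self-comparison of the initial pose).
    The truth record carries the achieved below-threshold fraction.
    """
    if klass not in _CLASS_BANDS:
        raise ValueError(f"unknown stability class {klass!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    lo, hi = _CLASS_BANDS[klass]
    p = rng.uniform(lo, hi)
    k_below = int(np.clip(round(p * n), 1, n))
    below = np.concatenate([[0.0], rng.uniform(0.5, 2.5, k_below - 1)])
    above = rng.uniform(threshold + 0.5, threshold + 3.5, n - k_below)
    values = np.concatenate([below, above])
    order = np.concatenate([[0], 1 + rng.permutation(n - 1)])
    values = values[np.argsort(order)]  # frame 1 stays at 0
    series = LigandRmsdSeries(
        compound_id=compound_id, receptor_id=receptor_id, values=values
    )
    truth = {
        "class": klass,
        "fraction_below_threshold": k_below / n,
        "threshold": threshold,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Compound library

_CLEAN_SMILES = (
    "c1ccccc1O",
    "CC(=O)Nc1ccc(O)cc1",
    "c1ccc2[nH]ccc2c1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "OCC1OC(O)C(O)C(O)C1O",
    "c1ccncc1",
    "CCN(CC)CC",
    "NC(=O)c1ccccc1",
    "Clc1ccccc1",
    "CCOC(=O)c1ccccc1N",
    "CC(=O)Oc1ccccc1C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CN1CCCC1c1cccnc1",
    "O=C(O)c1ccc(O)cc1",
    "CSc1ccccc1",
)
_METAL_SMILES = ("[Zn](Cl)Cl", "C[Sn](C)(C)C", "Cl[Hg]c1ccccc1", "[Fe]")
_HEAVY_SMILES = ("C" * 50, "C" * 55, "C" * 60)  # plain alkanes > 700 Da
_CHARGED_SMILES = (
    "[O-]C(=O)CCC(=O)[O-]",
    "[NH3+]CCCC[NH3+]",
    "[O-]S(=O)(=O)c1ccc(cc1)S(=O)(=O)[O-]",
)


def gen_compound_library(
    spec: SyntheticSpec, path: str | Path | None = None
) -> tuple[str, dict]:
    """Toy SDF library with controlled pre-filter violation fractions.

    ``filter_violation_fractions`` = (metal, mol_weight, net_charge); each
    violator breaks exactly one rule.  Returns the SDF text (also written
    to ``path`` if given) and a truth record mapping id -> violation.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rng = np.random.default_rng(spec.seed)
    n = spec.n_library
    f_metal, f_mw, f_charge = spec.filter_violation_fractions
    n_metal, n_mw, n_charge = (round(f * n) for f in (f_metal, f_mw, f_charge))
    categories = (
        ["metal"] * n_metal + ["mol_weight"] * n_mw + ["net_charge"] * n_charge
    )
    categories += ["none"] * (n - len(categories))
    categories = [categories[i] for i in rng.permutation(n)]

    pools = {
        "none": _CLEAN_SMILES,
        "metal": _METAL_SMILES,
        "mol_weight": _HEAVY_SMILES,
        "net_charge": _CHARGED_SMILES,
    }
    lines: list[str] = []
    truth: dict[str, str] = {}
    for i, cat in enumerate(categories, start=1):
        cid = f"SYN-{i:04d}"
        smiles = pools[cat][int(rng.integers(len(pools[cat])))]
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pools are static and valid; guard anyway
            raise RuntimeError(f"internal SMILES failed to parse: {smiles}")
        mol.SetProp("_Name", cid)
        AllChem.Compute2DCoords(mol)
        lines.append(Chem.MolToMolBlock(mol, kekulize=True))
        lines.append("$$$$\n")
        truth[cid] = cat
    sdf_text = "".join(lines)
    if path is not None:
        Path(path).write_text(sdf_text)
    return sdf_text, {"violations": truth}
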