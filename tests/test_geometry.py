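"""Superposition, RMSD, distance series, rotation angles and contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allokit.geometry import (
    AtomSpec,
    DegenerateInputError,
    contact_profile,
    distance_series,
    domain_rotation_angle,
    gatekeeper_series,
    rmsd_paired,
    superpose,
)
from allokit.structio import DEFAULT_DOMAIN_MAP, Structure, Trajectory
from allokit import synthdata as sd
from conftest import random_rotation
from helpers_oracles import quaternion_rmsd


def _structure(names, elements, res_names, res_seqs, coords, chain="A"):
    n = len(names)
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(names),
        element=np.array(elements),
        alt_loc=np.array([""] * n),
        res_name=np.array(res_names),
        chain_id=np.array([chain] * n),
        res_seq=np.array(res_seqs),
        coords=np.array(coords, dtype=float),
    )


class TestSuperpose:
    def test_identity_on_self(self, rng):
        X = rng.normal(size=(10, 3))
        sp = superpose(X, X)
        np.testing.assert_allclose(sp.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(sp.translation, 0.0, atol=1e-10)
        assert sp.rmsd_after == pytest.approx(0.0, abs=1e-10)

    def test_recovers_planted_rotation_translation(self, rng):
        X = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Y = X @ R.T + np.array([3.0, 4.0, 0.0])
        sp = superpose(X, Y)
        assert sp.angle_deg == pytest.approx(90.0, abs=1e-8)
        assert sp.rmsd_after == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_oracle_with_perturbation(self, rng):
        X = rng.normal(size=(8, 3))
        Y = X @ random_rotation(rng).T + rng.normal(size=3) + 0.1 * rng.normal(size=(8, 3))
        assert superpose(X, Y).rmsd_after == pytest.approx(
            quaternion_rmsd(X, Y), abs=1e-8
        )

    def test_weighted_fit_prioritizes_heavy_points(self, rng):
        X = rng.normal(size=(6, 3))
        Y = X.copy()
        Y[0] += 10.0  # outlier
        w = np.array([0.0, 1, 1, 1, 1, 1])
        sp = superpose(Y, X, weights=w)
        assert sp.rmsd_after == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateInputError):
            superpose(line, line)


class TestRmsdPaired:
    def test_translation_only(self, rng):
        A = rng.normal(size=(7, 3))
        B = A + np.array([3.0, 4.0, 0.0])
        assert rmsd_paired(A, B, fit=False) == pytest.approx(5.0)
        assert rmsd_paired(A, B, fit=True) == pytest.approx(0.0, abs=1e-10)

    def test_equals_brute_force_sum(self, rng):
        A = rng.normal(size=(9, 3))
        B = rng.normal(size=(9, 3))
        brute = np.sqrt(sum(np.sum((a - b) ** 2) for a, b in zip(A, B)) / 9)
        assert rmsd_paired(A, B, fit=False) == pytest.approx(brute, abs=1e-12)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            rmsd_paired(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_fitted_rmsd_invariant_under_rigid_motion(self, rng):
        A = rng.normal(size=(15, 3))
        B = rng.normal(size=(15, 3))
        base = rmsd_paired(A, B, fit=True)
        for _ in range(5):
            A2 = A @ random_rotation(rng).T + rng.normal(size=3) * 10
            assert rmsd_paired(A2, B, fit=True) == pytest.approx(base, abs=1e-8)


class TestDistanceSeries:
    def test_constant_distance(self):
        s = _structure(["CA", "CA"], ["C", "C"], ["ALA", "GLY"], [1, 2],
                       [[0, 0, 0], [6, 0, 0]])
        traj = Trajectory(topology=s, frames=np.repeat(s.coords[None], 4, axis=0))
        ds = distance_series(traj, 1, 2)
        np.testing.assert_allclose(ds.values, 6.0)

    def test_planted_shift_recovered(self, toy_receptor):
        # move residue 113 a further 8 A along the 113->495 pair axis so the
        # planted distance shift is exactly +8
        a = toy_receptor.coords[
            (toy_receptor.res_seq == 113) & (toy_receptor.name == "CA")
        ][0]
        b = toy_receptor.coords[
            (toy_receptor.res_seq == 495) & (toy_receptor.name == "CA")
        ][0]
        u = (a - b) / np.linalg.norm(a - b)
        spec = sd.SyntheticSpec(
            seed=5, n_frames=100, fluctuation_sigma=0.3,
            planted_events=(sd.Event(start_frame=51, residues=(113,),
                                     translation=tuple(8.0 * u)),),
        )
        traj = sd.gen_trajectory(toy_receptor, spec)
        ds = distance_series(traj, AtomSpec(113, "CA"), AtomSpec(495, "CA"))
        shift = ds.values[50:].mean() - ds.values[:50].mean()
        assert shift == pytest.approx(8.0, abs=0.3)

    def test_ambiguous_spec_lists_matches(self):
        s = _structure(["CA", "CA"], ["C", "C"], ["ALA", "ALA"], [1, 1],
                       [[0, 0, 0], [1, 0, 0]])
        traj = Trajectory(topology=s, frames=s.coords[None])
        with pytest.raises(ValueError, match="ambiguous"):
            distance_series(traj, AtomSpec(1, "CA"), AtomSpec(1, "CA"))


class TestDomainRotation:
    def test_zero_for_identical_structures(self, toy_receptor):
        assert domain_rotation_angle(
            toy_receptor, toy_receptor, DEFAULT_DOMAIN_MAP, "PTP", "C-SH2"
        ) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [30.0, 90.0, 150.0])
    def test_recovers_planted_domain_rotation(self, toy_receptor, rng, angle):
        mask = (toy_receptor.res_seq >= 112) & (toy_receptor.res_seq <= 216)
        coords = toy_receptor.coords.copy()
        ca_centroid = coords[mask & (toy_receptor.name == "CA")].mean(0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        coords[mask] = (coords[mask] - ca_centroid) @ R.T + ca_centroid
        sB = toy_receptor.with_coords(coords)
        got = domain_rotation_angle(
            toy_receptor, sB, DEFAULT_DOMAIN_MAP, "PTP", "C-SH2"
        )
        assert got == pytest.approx(angle, abs=1e-6)
        # symmetry
        rev = domain_rotation_angle(
            sB, toy_receptor, DEFAULT_DOMAIN_MAP, "PTP", "C-SH2"
        )
        assert rev == pytest.approx(got, abs=1e-6)

    def test_too_few_shared_ca_raises(self, toy_receptor):
        from allokit.structio import DomainMap

        dm = DomainMap({"tiny": [(8, 8)], "PTP": [(221, 524)]})
        with pytest.raises(Exception, match="shared CA|matched no atoms"):
            domain_rotation_angle(toy_receptor, toy_receptor, dm, "PTP", "tiny")


class TestGatekeeperSeries:
    def test_close_pair_reads_2p8(self):
        s = _structure(
            ["CA", "NH1", "CA", "OE1"],
            ["C", "N", "C", "O"],
            ["ARG", "ARG", "GLU", "GLU"],
            [23, 23, 176, 176],
            [[0, 0, 0], [2, 0, 0], [6, 0, 0], [4.8, 0, 0]],
        )
        traj = Trajectory(topology=s, frames=s.coords[None])
        ca, no = gatekeeper_series(traj, 23, 176)
        assert no.values[0] == pytest.approx(2.8)
        assert bool(no.values[0] <= 3.5)  # salt bridge under the 3.5 A rule
        assert ca.values[0] == pytest.approx(6.0)

    def test_distant_pair_is_open(self, toy_trajectory):
        # generator default: gatekeepers start ~17 A apart, no salt bridge
        ca, no = gatekeeper_series(toy_trajectory, 23, 176)
        assert ca.values.mean() == pytest.approx(17.0, abs=1.0)
        assert (no.values > 3.5).all()

    def test_uncharged_residues_rejected(self):
        s = _structure(
            ["CA", "CB", "CA"],
            ["C", "C", "C"],
            ["ALA", "ALA", "GLY"],
            [1, 1, 2],
            [[0, 0, 0], [1, 0, 0], [5, 0, 0]],
        )
        traj = Trajectory(topology=s, frames=s.coords[None])
        with pytest.raises(ValueError, match="ALA1|GLY2"):
            gatekeeper_series(traj, 1, 2)


class TestContactProfile:
    def test_hbond_geometry(self):
        rec = _structure(["O"], ["O"], ["ALA"], [1], [[0, 0, 0]])
        lig = _structure(["N1", "H1"], ["N", "H"], ["LIG", "LIG"], [900, 900],
                         [[0, 0, 2.9], [0, 0.25, 1.95]], chain="L")
        prof = contact_profile(rec, lig)
        assert prof.count("hbond") == 1

    def test_hbond_rejected_at_bad_angle(self):
        rec = _structure(["O"], ["O"], ["ALA"], [1], [[0, 0, 0]])
        # H points away from the acceptor: D-H...A angle near 0
        lig = _structure(["N1", "H1"], ["N", "H"], ["LIG", "LIG"], [900, 900],
                         [[0, 0, 2.9], [0, 0, 3.9]], chain="L")
        assert contact_profile(rec, lig).count("hbond") == 0

    def test_hydrophobic_contact(self):
        rec = _structure(["CG"], ["C"], ["LEU"], [2], [[0, 0, 0]])
        lig = _structure(["C1"], ["C"], ["LIG"], [900], [[4.0, 0, 0]], chain="L")
        assert contact_profile(rec, lig).count("hydrophobic") == 1

    def test_cation_pi_above_ring(self):
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ring = [[1.4 * np.cos(a), 1.4 * np.sin(a), 0.0] for a in angles]
        rec = _structure(names, ["C"] * 6, ["PHE"] * 6, [10] * 6, ring)
        lig = _structure(["N1"], ["N"], ["LIG"], [900], [[0, 0, 5.0]], chain="L")
        prof = contact_profile(rec, lig, ligand_charges={0: 1})
        assert prof.count("cation_pi") == 1
        # at 7 A it is out of range
        lig_far = _structure(["N1"], ["N"], ["LIG"], [900], [[0, 0, 7.0]], chain="L")
        assert contact_profile(rec, lig_far, ligand_charges={0: 1}).count("cation_pi") == 0

    def test_salt_bridge_needs_opposite_charges(self):
        rec = _structure(["OE1"], ["O"], ["GLU"], [15], [[0, 0, 0]])
        lig = _structure(["N1"], ["N"], ["LIG"], [900], [[0, 0, 3.0]], chain="L")
        assert contact_profile(rec, lig, ligand_charges={0: 1}).count("salt_bridge") == 1
        assert contact_profile(rec, lig, ligand_charges={0: -1}).count("salt_bridge") == 0

    def test_counts_monotone_in_cutoffs(self, rng):
        n = 12
        rec = _structure(
            ["CG"] * n, ["C"] * n, ["LEU"] * n, list(range(1, n + 1)),
            rng.uniform(-6, 6, size=(n, 3)),
        )
        lig = _structure(
            ["C1", "C2", "C3"], ["C"] * 3, ["LIG"] * 3, [900] * 3,
            rng.uniform(-2, 2, size=(3, 3)), chain="L",
        )
        counts = [
            contact_profile(rec, lig, hydrophobic_cutoff=c).count("hydrophobic")
            for c in (5.5, 4.5, 3.5, 2.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_ligand_rejected(self, toy_receptor):
        lig = _structure(["C1"], ["C"], ["LIG"], [900], [[0, 0, 0]], chain="L")
        with pytest.raises(ValueError):
            contact_profile(toy_receptor, lig.subset(np.array([False])))
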