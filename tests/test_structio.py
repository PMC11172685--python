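"""Structure/compound/score-table I/O and atom-selection semantics."""

import numpy as np
import pandas as pd
import pytest

from allokit.structio import (
    DEFAULT_DOMAIN_MAP,
    DomainMap,
    EmptySelectionError,
    ScoreTable,
    Structure,
    StructureFormatError,
    Trajectory,
    read_compounds,
    read_score_table,
    read_structure,
    select_atoms,
    write_structure,
)

#: Standard average atomic masses for the independent MW oracle.
ATOMIC_MASS = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Se": 78.971, "Br": 79.904, "I": 126.904, "Zn": 65.38, "Sn": 118.71,
    "Hg": 200.59, "Fe": 55.845,
}


def _make_residue(res_seq, res_name, atom_names, elements=None, chain="A"):
    n = len(atom_names)
    elements = elements or [a[0] for a in atom_names]
    return dict(
        serial=np.arange(1, n + 1),
        name=np.array(atom_names),
        element=np.array(elements),
        alt_loc=np.array([""] * n),
        res_name=np.array([res_name] * n),
        chain_id=np.array([chain] * n),
        res_seq=np.array([res_seq] * n),
        coords=np.arange(3 * n, dtype=float).reshape(n, 3),
    )


class TestReadStructure:
    def test_single_atom_file(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A  42      11.000  22.000  33.000  1.00  0.00"
            "           C\nEND\n"
        )
        s = read_structure(p)
        assert isinstance(s, Structure)
        assert s.n_atoms == 1
        assert s.res_seq[0] == 42
        np.testing.assert_allclose(s.coords[0], [11.0, 22.0, 33.0])

    def test_multi_model_yields_trajectory(self, tmp_path, toy_receptor):
        traj = Trajectory(
            topology=toy_receptor,
            frames=np.repeat(toy_receptor.coords[None], 3, axis=0)
            + np.arange(3)[:, None, None],
        )
        p = tmp_path / "traj.pdb"
        write_structure(traj, p)
        back = read_structure(p, model_policy="all")
        assert isinstance(back, Trajectory)
        assert back.n_frames == 3
        assert back.topology.n_atoms == toy_receptor.n_atoms
        # model_policy="first" returns only the first model
        first = read_structure(p, model_policy="first")
        assert isinstance(first, Structure)

    def test_model_atom_count_mismatch_is_error(self, tmp_path):
        line = "ATOM  {serial:>5}  CA  ALA A{res:>4}       0.000   0.000   0.000  1.00  0.00           C\n"
        text = (
            "MODEL        1\n" + line.format(serial=1, res=1)
            + line.format(serial=2, res=2) + "ENDMDL\n"
            "MODEL        2\n" + line.format(serial=1, res=1) + "ENDMDL\nEND\n"
        )
        p = tmp_path / "bad.pdb"
        p.write_text(text)
        with pytest.raises(StructureFormatError, match="atom count|topology"):
            read_structure(p, model_policy="all")

    def test_unparseable_atom_line_names_line_number(self, tmp_path):
        p = tmp_path / "broken.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1      xx.xxx   0.000   0.000  1.00  0.00"
            "           C\n"
        )
        with pytest.raises(StructureFormatError, match=":1:"):
            read_structure(p)

    def test_round_trip_preserves_order_numbering_coords(self, tmp_path, toy_receptor):
        p = tmp_path / "rt.pdb"
        write_structure(toy_receptor, p)
        back = read_structure(p)
        assert np.array_equal(back.res_seq, toy_receptor.res_seq)
        assert np.array_equal(back.name, toy_receptor.name)
        assert np.array_equal(back.chain_id, toy_receptor.chain_id)
        np.testing.assert_allclose(back.coords, toy_receptor.coords, atol=5.1e-4)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert s.n_atoms == 1
        np.testing.assert_allclose(s.coords[0], [5.0, 0.0, 0.0])


class TestSelectAtoms:
    def test_heavy_to_cb_drops_side_chain_beyond_cb(self):
        s = Structure(**_make_residue(1, "LYS", ["N", "CA", "C", "O", "CB", "CG", "CD"]))
        out = select_atoms(s, atom_class="heavy_to_CB")
        assert sorted(out.name) == ["C", "CA", "CB", "N", "O"]

    def test_glycine_heavy_to_cb(self):
        s = Structure(**_make_residue(2, "GLY", ["N", "CA", "C", "O"]))
        out = select_atoms(s, atom_class="heavy_to_CB")
        assert out.n_atoms == 4

    def test_hydrogens_excluded_from_heavy_classes(self):
        s = Structure(**_make_residue(
            3, "ALA", ["N", "H", "CA", "HA", "C", "O", "CB"],
            elements=["N", "H", "C", "H", "C", "O", "C"],
        ))
        assert select_atoms(s, atom_class="heavy").n_atoms == 5
        assert select_atoms(s, atom_class="heavy_to_CB").n_atoms == 5
        assert select_atoms(s, atom_class="all").n_atoms == 7

    def test_ca_selection_one_atom_per_residue_in_order(self, toy_receptor):
        ca = select_atoms(toy_receptor, atom_class="CA")
        assert np.array_equal(ca.name, np.full(ca.n_atoms, "CA"))
        assert sorted(ca.res_seq.tolist()) == ca.res_seq.tolist()
        assert len(set(ca.res_seq.tolist())) == ca.n_atoms

    def test_empty_selection_raises(self, toy_receptor):
        with pytest.raises(EmptySelectionError):
            select_atoms(toy_receptor, chain="Z")

    def test_chain_and_atom_class_commute(self, toy_receptor):
        a = select_atoms(select_atoms(toy_receptor, chain="A"), atom_class="CA")
        b = select_atoms(select_atoms(toy_receptor, atom_class="CA"), chain="A")
        assert np.array_equal(a.serial, b.serial)
        # idempotent
        c = select_atoms(a, atom_class="CA")
        assert np.array_equal(a.serial, c.serial)


class TestDomainMap:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DomainMap({"A": [(1, 50)], "B": [(40, 90)]})

    def test_default_map_covers_named_domains(self):
        assert DEFAULT_DOMAIN_MAP.domain_of(50) == "N-SH2"
        assert DEFAULT_DOMAIN_MAP.domain_of(150) == "C-SH2"
        assert DEFAULT_DOMAIN_MAP.domain_of(300) == "PTP"
        assert DEFAULT_DOMAIN_MAP.domain_of(108) is None  # linker


class TestReadCompounds:
    def test_benzene_weight_charge_elements(self, tmp_path):
        p = tmp_path / "lib.smi"
        p.write_text("c1ccccc1 benzene\nCC(=O)[O-] acetate\n")
        recs = read_compounds(p, fmt="smiles")
        ben = next(r for r in recs if r.id == "benzene")
        # oracle: 6 C + 6 H from standard masses
        expected = 6 * ATOMIC_MASS["C"] + 6 * ATOMIC_MASS["H"]
        assert ben.mol_weight == pytest.approx(expected, abs=0.02)
        assert ben.net_charge == 0
        assert ben.elements == {"C", "H"}
        ace = next(r for r in recs if r.id == "acetate")
        assert ace.net_charge == -1

    def test_iron_compound_reports_fe(self, tmp_path):
        p = tmp_path / "fe.smi"
        p.write_text("[Fe] iron\n")
        recs = read_compounds(p, fmt="smiles")
        assert "Fe" in recs[0].elements

    def test_unparseable_record_skipped(self, tmp_path):
        p = tmp_path / "mix.smi"
        p.write_text("c1ccccc1 ok\nnot_a_smiles bad\nCCO ethanol\n")
        recs = read_compounds(p, fmt="smiles")
        assert [r.id for r in recs] == ["ok", "ethanol"]

    def test_mol_weight_matches_atomic_mass_oracle(self, tmp_path, rng):
        """MW from the reader vs direct summation over a formula-randomized set."""
        from rdkit import Chem

        fragments = ["C", "CC", "CCO", "c1ccccc1", "CN", "CCl", "C(=O)O", "CS"]
        smiles = ["".join(rng.choice(fragments, size=rng.integers(1, 4)))
                  for _ in range(100)]
        p = tmp_path / "rand.smi"
        p.write_text("".join(f"{s} m{i}\n" for i, s in enumerate(smiles)))
        recs = read_compounds(p, fmt="smiles")
        for rec in recs:
            mol = Chem.AddHs(Chem.MolFromSmiles(smiles[int(rec.id[1:])]))
            oracle = sum(ATOMIC_MASS[a.GetSymbol()] for a in mol.GetAtoms())
            assert rec.mol_weight == pytest.approx(oracle, abs=0.02)


class TestScoreTable:
    def test_published_tables_have_expected_ids(self):
        from allokit.datasets import load_hvi_hits, load_tba_hits

        tba = load_tba_hits()
        hvi = load_hvi_hits()
        for rec in tba.receptors:
            sub = tba.df[tba.df["receptor_id"] == rec]
            assert sub["compound_id"].nunique() == 18
        assert len(tba.compounds) == 18
        assert len(hvi.compounds) == 21

    def test_empty_table_with_header_warns(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("compound_id,receptor_id,affinity\n")
        with pytest.warns(UserWarning, match="empty"):
            st = read_score_table(p)
        assert len(st.df) == 0

    def test_non_numeric_affinity_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "compound_id,receptor_id,affinity\na,r,-7.0\nb,r,oops\n"
        )
        with pytest.raises(ValueError, match=":3:"):
            read_score_table(p)

    def test_duplicate_pose_rejected(self):
        df = pd.DataFrame(
            {
                "compound_id": ["a", "a"],
                "receptor_id": ["r", "r"],
                "affinity": [-7.0, -7.5],
                "pose_rank": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            ScoreTable(df)
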