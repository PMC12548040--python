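from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import bcrforest as bf
from bcrforest.structure import Residue
from oracles import quaternion_rmsd


def _model(coords, node_id="m", plddt=None, code="A", chain="H", role="antibody"):
    coords = np.asarray(coords, float)
    plddt = plddt if plddt is not None else [80.0] * len(coords)
    residues = [Residue(name="ALA", code=code, ca=coords[i], plddt=float(plddt[i]),
                        resid=str(i + 1)) for i in range(len(coords))]
    return bf.StructureModel(node_id=node_id, chains={chain: residues},
                             roles={chain: role})


class TestPdbIO:
    def test_minimal_three_residues(self, tmp_path):
        m = _model([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]],
                   plddt=[90.1, 85.0, 70.2])
        path = tmp_path / "m.pdb"
        bf.write_pdb(m, path)
        back = bf.read_pdb(path, chain_roles={"H": "antibody"})
        assert list(back.chains) == ["H"]
        assert len(back.chains["H"]) == 3
        assert back.mean_plddt() == pytest.approx((90.1 + 85.0 + 70.2) / 3, abs=1e-6)

    def test_roundtrip_coordinates(self, tmp_path):
        rng = np.random.default_rng(2)
        m = _model(rng.uniform(-20, 20, size=(10, 3)))
        bf.write_pdb(m, tmp_path / "m.pdb")
        back = bf.read_pdb(tmp_path / "m.pdb")
        np.testing.assert_allclose(back.coords(), np.round(m.coords(), 3), atol=5e-4)

    def test_no_atoms_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(bf.StructureError):
            bf.read_pdb(p)


class TestSuperposeRmsd:
    def test_identical_zero(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-10, 10, size=(8, 3))
        assert bf.superpose_rmsd(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-10, 10, size=(12, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        y = x @ rot.T + np.array([0.0, 0.0, 5.0])
        assert bf.superpose_rmsd(x, y) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_and_displacement(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-10, 10, size=(4, 3))
        y = x.copy()
        y[2] += [2.0, 0.0, 0.0]
        ab = bf.superpose_rmsd(x, y)
        ba = bf.superpose_rmsd(y, x)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert 0 < ab <= 2.0 / np.sqrt(4) + 1e-9 or ab > 0  # bounded above by raw shift

    def test_matches_quaternion_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            x = rng.uniform(-15, 15, size=(int(rng.integers(4, 20)), 3))
            y = x + rng.normal(scale=1.0, size=x.shape)
            assert bf.superpose_rmsd(x, y) == \
                pytest.approx(quaternion_rmsd(x, y), abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(bf.StructureError):
            bf.superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestBiophysics:
    def test_kyte_doolittle_alanine(self):
        hydro, _ = bf.biophysics("A")
        assert hydro == pytest.approx(1.8)

    def test_net_charge_counting(self):
        assert bf.biophysics("GKDE")[1] == -1
        assert bf.biophysics("KR")[1] == 2
        assert bf.biophysics("H")[1] == 0  # histidine neutral

    def test_x_excluded_from_mean(self):
        hydro, _ = bf.biophysics("AX")
        assert hydro == pytest.approx(1.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bf.biophysics("")


class TestLineageStructureReport:
    def _chain_tree(self):
        t = bf.LineageTree.empty("germline", tree_id="x")
        prev = "germline"
        for i, w in enumerate([1, 2, 3], 1):
            t.add_node(f"v{i}", kind=bf.SAMPLED, sequence_aa="A" * 12)
            t.add_edge(prev, f"v{i}", w)
            prev = f"v{i}"
        t.graph.nodes["germline"]["sequence_aa"] = "A" * 12
        return t

    def test_identical_structures(self):
        t = self._chain_tree()
        base = np.arange(36, dtype=float).reshape(12, 3)
        structures = {n: _model(base, node_id=n) for n in t.graph.nodes}
        rep = bf.lineage_structure_report(t, structures)
        assert np.allclose(rep.nodes["rmsd_to_germline"], 0.0)
        assert rep.correlations["edge_rmsd_vs_weight"] == "zero variance"

    def test_monotone_displacement_gives_perfect_edge_correlation(self):
        t = self._chain_tree()
        base = np.arange(36, dtype=float).reshape(12, 3)
        coords = {"germline": base.copy()}
        # each edge displaces (weight) residues by (weight) angstroms: edge
        # RMSD strictly increases with edge weight
        prev, start = "germline", 0
        for i, w in enumerate([1, 2, 3], 1):
            c = coords[prev].copy()
            for j in range(w):
                c[start + j] += [float(w), 0.0, 0.0]
            start += w
            coords[f"v{i}"] = c
            prev = f"v{i}"
        structures = {n: _model(c, node_id=n) for n, c in coords.items()}
        rep = bf.lineage_structure_report(t, structures)
        assert rep.correlations["edge_rmsd_vs_weight"] == pytest.approx(1.0)
        assert rep.correlations["node_rmsd_vs_germline_distance"] == pytest.approx(1.0)

    def test_missing_structures_listed(self):
        t = self._chain_tree()
        base = np.arange(36, dtype=float).reshape(12, 3)
        structures = {n: _model(base, node_id=n) for n in ["germline", "v1", "v2"]}
        rep = bf.lineage_structure_report(t, structures)
        assert rep.skipped == ["v3"]
        assert set(rep.nodes.index) == {"germline", "v1", "v2"}

    def test_missing_germline_rejected(self):
        t = self._chain_tree()
        with pytest.raises(bf.StructureError):
            bf.lineage_structure_report(t, {})


class TestInterface:
    def _complex(self, ag_offset):
        ab = _model(np.arange(15, dtype=float).reshape(5, 3) * 2.0, role="antibody")
        ag_coords = np.arange(15, dtype=float).reshape(5, 3) * 2.0 + ag_offset
        ag = [Residue(name="GLY", code="G", ca=ag_coords[i], plddt=70.0,
                      resid=str(i + 1)) for i in range(5)]
        ab.chains["A"] = ag
        ab.roles["A"] = "antigen"
        return ab

    def test_far_apart_empty(self):
        rep = bf.interface_residues(self._complex(np.array([100.0, 0, 0])))
        assert rep.size == 0
        assert not rep.antibody_residues

    def test_single_contact_at_threshold(self):
        ab = _model(np.array([[0.0, 0, 0], [50, 0, 0], [100, 0, 0]]), role="antibody")
        ag_coords = np.array([[4.9, 0.0, 0.0], [200.0, 0, 0], [300.0, 0, 0]])
        ab.chains["A"] = [Residue(name="GLY", code="G", ca=ag_coords[i], plddt=70.0,
                                  resid=str(i + 1)) for i in range(3)]
        ab.roles["A"] = "antigen"
        rep = bf.interface_residues(ab, cutoff_angstrom=5.0)
        assert rep.size == 1
        assert rep.antibody_residues == {("H", "1")}
        assert rep.antigen_residues == {("A", "1")}

    def test_matches_all_pairs_bruteforce(self):
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            ab_xyz = rng.uniform(0, 30, size=(12, 3))
            ag_xyz = rng.uniform(0, 30, size=(9, 3))
            ab = _model(ab_xyz, role="antibody")
            ab.chains["A"] = [Residue(name="GLY", code="G", ca=ag_xyz[i], plddt=70.0,
                                      resid=str(i + 1)) for i in range(9)]
            ab.roles["A"] = "antigen"
            rep = bf.interface_residues(ab, cutoff_angstrom=8.0)
            expected_ab = {("H", str(i + 1)) for i in range(12)
                           if any(np.linalg.norm(ab_xyz[i] - ag_xyz[j]) <= 8.0
                                  for j in range(9))}
            expected_ag = {("A", str(j + 1)) for j in range(9)
                           if any(np.linalg.norm(ab_xyz[i] - ag_xyz[j]) <= 8.0
                                  for i in range(12))}
            assert rep.antibody_residues == expected_ab
            assert rep.antigen_residues == expected_ag

    def test_missing_antigen_role(self):
        ab = _model(np.zeros((4, 3)), role="antibody")
        with pytest.raises(bf.StructureError):
            bf.interface_residues(ab)

    def test_gained_lost_vs_germline(self):
        germ = self._complex(np.array([3.0, 0, 0]))
        variant = self._complex(np.array([100.0, 0, 0]))
        change = bf.interface_change_vs_germline(germ, variant)
        assert change["gained"] == []
        assert len(change["lost"]) == 5
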