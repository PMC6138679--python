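"""Dihedral, pucker, perturbation, filtering and clustering tests."""

import numpy as np
import pytest
import biotite.structure as struc

from collagen_gpo import geometry, synth
from collagen_gpo.errors import ParameterError, StructureError
from collagen_gpo.geometry import (
    Conformer,
    FilterWindow,
    PerturbationSpec,
    Residue,
    TripleHelixModel,
    backbone_span,
    build_chain,
    cluster_conformers,
    dihedral,
    perturb,
    phi_psi,
    ppii_filter,
    read_structure,
    ring_pucker,
    wrap_angle,
    write_structure,
)
from conftest import mean_plane_pucker_oracle

RNG = np.random.default_rng(20260918)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        p = [np.array(x, float) for x in
             [(1, 1, 0), (0, 1, 0), (0, 0, 0), (1, 0, 0)]]
        assert dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        p = [np.array(x, float) for x in
             [(1, 1, 0), (0, 1, 0), (0, 0, 0), (-1, 0, 0)]]
        assert dihedral(*p) == pytest.approx(180.0, abs=1e-12)

    @staticmethod
    def projection_oracle(p1, p2, p3, p4):
        """Independent construction: project the flanking bonds onto the
        plane normal to the central bond and take their signed angle."""
        b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
        b2u = b2 / np.linalg.norm(b2)
        u = -b1 + np.dot(b1, b2u) * b2u
        w = b3 - np.dot(b3, b2u) * b2u
        x = np.dot(u, w)
        y = np.dot(np.cross(b2u, u), w)
        return float(np.degrees(np.arctan2(y, x)))

    def test_matches_independent_vector_algebra_oracle(self):
        for _ in range(50):
            pts = RNG.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except ParameterError:
                continue
            oracle = self.projection_oracle(*pts)
            diff = abs(((ours - oracle + 180) % 360) - 180)
            assert diff < 1e-9
            # third opinion from the structural-biology library (float32)
            lib = float(np.degrees(struc.dihedral(*pts)))
            assert abs(((ours - lib + 180) % 360) - 180) < 1e-3

    def test_reversal_and_mirror_symmetries(self):
        for _ in range(20):
            pts = RNG.normal(size=(4, 3)) * 3
            try:
                d = dihedral(*pts)
            except ParameterError:
                continue
            assert dihedral(*pts[::-1]) == pytest.approx(d, abs=1e-9)
            mirrored = pts.copy()
            mirrored[:, 2] *= -1
            if abs(abs(d) - 180.0) > 1e-6:  # sign of ±180 is a wrap artefact
                assert dihedral(*mirrored) == pytest.approx(-d, abs=1e-9)

    def test_degenerate_input_raises(self):
        a = np.zeros(3)
        b = np.array([1.0, 0, 0])
        with pytest.raises(ParameterError):
            dihedral(a, b, b, a)

    @pytest.mark.parametrize("raw, wrapped", [(180.5, -179.5), (-180.0, 180.0),
                                              (540.0, 180.0), (10.0, 10.0)])
    def test_wrap_rule(self, raw, wrapped):
        assert wrap_angle(raw) == pytest.approx(wrapped)


class TestPhiPsi:
    def test_built_chain_recovers_requested_angles(self):
        residues = build_chain("GGGGG", phi=-75.0, psi=150.0)
        model = TripleHelixModel({"A": residues})
        for rid in (2, 3, 4):
            rc = phi_psi(model, "A", rid)
            assert rc.phi == pytest.approx(-75.0, abs=0.01)
            assert rc.psi == pytest.approx(150.0, abs=0.01)

    def test_terminal_residues_have_undefined_members(self):
        residues = build_chain("GGG")
        model = TripleHelixModel({"A": residues})
        assert phi_psi(model, "A", 1).phi is None
        assert phi_psi(model, "A", 3).psi is None


class TestRingPucker:
    def build_single_pro(self, pucker, displacement=0.4):
        res = build_chain("PG", puckers={1: pucker}, ring_displacement=displacement)
        return TripleHelixModel({"A": res})

    def test_constructed_endo_and_exo(self):
        endo = self.build_single_pro("endo")
        assert ring_pucker(endo, "A", 1).state == "endo"
        assert ring_pucker(endo, "A", 1).cg_displacement == pytest.approx(0.4, abs=1e-6)
        exo = self.build_single_pro("exo")
        assert ring_pucker(exo, "A", 1).state == "exo"

    def test_small_displacement_is_planar(self):
        model = self.build_single_pro("endo", displacement=0.05)
        assert ring_pucker(model, "A", 1).state == "planar"

    def test_invariant_under_rigid_motion(self):
        model = self.build_single_pro("exo")
        base = ring_pucker(model, "A", 1)
        theta = 1.1
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = model.copy()
        for res in moved.chains["A"]:
            for name in res.atoms:
                res.atoms[name] = rot @ res.atoms[name] + np.array([5.0, -3.0, 8.0])
        after = ring_pucker(moved, "A", 1)
        assert after.state == base.state
        assert after.cg_displacement == pytest.approx(base.cg_displacement, abs=1e-9)

    def test_agrees_with_pseudorotation_oracle_on_randomized_rings(self):
        """100 random puckered rings: the package's N-CA-CD plane rule and
        the 5-atom mean-plane oracle give the same state."""
        rng = np.random.default_rng(7)
        n_checked = 0
        while n_checked < 100:
            disp = float(rng.uniform(0.25, 0.6)) * (1 if rng.random() < 0.5 else -1)
            state = "endo" if disp > 0 else "exo"
            res = build_chain("PG", puckers={1: state}, ring_displacement=abs(disp))
            model = TripleHelixModel({"A": res})
            got = ring_pucker(model, "A", 1).state
            oracle = mean_plane_pucker_oracle(model.residue("A", 1))
            assert got == oracle == state
            n_checked += 1

    def test_non_imino_residue_rejected(self):
        model = TripleHelixModel({"A": build_chain("GG")})
        with pytest.raises(StructureError):
            ring_pucker(model, "A", 1)


class TestPerturb:
    @pytest.fixture()
    def helix(self):
        model, _ = synth.gen_triple_helix(synth.HelixConfig(n_triplets=8), seed=2)
        return model

    def groups(self, model):
        return geometry.standard_rotation_groups(model, "C", 10)  # 4th triplet P

    def test_zero_amplitude_is_identity(self, helix):
        spec = PerturbationSpec(self.groups(helix), 0.0, 2, seed=9)
        conf = perturb(helix, spec)[0]
        for key, coord in helix.iter_atoms():
            assert np.allclose(conf.model.atom(*key), coord, atol=1e-9)

    def test_rigid_groups_preserve_internal_distances(self, helix):
        graph = geometry.bond_graph(helix)
        groups = self.groups(helix)
        moving = geometry.rotating_atoms(graph, *groups[0])
        spec = PerturbationSpec((groups[0],), 30.0, 3, seed=4)
        for conf in perturb(helix, spec):
            keys = sorted(moving | set(groups[0]))
            before = np.array([helix.atom(*k) for k in keys])
            after = np.array([conf.model.atom(*k) for k in keys])
            d_before = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
            d_after = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
            assert np.allclose(d_before, d_after, atol=1e-9)

    def test_ring_tip_rotation_leaves_other_backbones_fixed(self, helix):
        tip = (("C", 10, "CB"), ("C", 10, "CD"))
        spec = PerturbationSpec((tip,), 40.0, 1, seed=5)
        conf = perturb(helix, spec)[0]
        for key, coord in helix.iter_atoms():
            cid, rid, name = key
            if (cid, rid) == ("C", 10) and name == "CG":
                continue
            assert np.allclose(conf.model.atom(*key), coord, atol=1e-12)

    def test_disconnected_axis_rejected(self, helix):
        graph = geometry.bond_graph(helix)
        with pytest.raises(ParameterError):
            geometry.rotating_atoms(graph, ("A", 1, "N"), ("B", 1, "N"))

    def test_seeded_reproducibility(self, helix):
        spec = PerturbationSpec(self.groups(helix), 20.0, 5, seed=3)
        a = perturb(helix, spec)
        b = perturb(helix, spec)
        assert all(x.angles == y.angles for x, y in zip(a, b))


class TestPpiiFilter:
    @pytest.mark.parametrize("phi, psi, ok", [
        (-70.0, 150.0, True),   # well inside the collagen window
        (-40.0, 150.0, False),
        (-50.0, 170.0, True),   # closed boundary accepted
        (-90.0, 130.0, True),
        (-90.1, 150.0, False),
        (-70.0, 170.1, False),
    ])
    def test_window_boundaries(self, phi, psi, ok):
        assert FilterWindow().contains(phi, psi) is ok

    def test_identity_perturbation_of_in_window_model_accepted(self):
        model, _ = synth.gen_triple_helix(synth.HelixConfig(n_triplets=6), seed=1)
        groups = geometry.standard_rotation_groups(model, "C", 7)
        spec = PerturbationSpec(groups, 0.0, 5, seed=2)
        conformers = perturb(model, spec)
        accepted = ppii_filter(conformers, [("C", 7), ("C", 8)])
        assert len(accepted) == len(conformers)

    def test_bad_window_rejected(self):
        with pytest.raises(ParameterError):
            FilterWindow(phi_min=-50.0, phi_max=-90.0)


class TestClustering:
    def conformers_at(self, angle_pairs):
        out = []
        for i, (phi, psi) in enumerate(angle_pairs):
            model = TripleHelixModel({"A": build_chain("GPG", phi=phi, psi=psi)})
            out.append(Conformer(model, (), i))
        return out

    def test_duplicates_form_one_cluster(self):
        confs = self.conformers_at([(-75, 150)] * 4)
        clusters = cluster_conformers(confs, [("A", 2)])
        assert len(clusters) == 1
        assert clusters[0].size == 4

    def test_separated_conformers_form_two_clusters(self):
        confs = self.conformers_at([(-75, 150), (-55, 150)])
        assert len(cluster_conformers(confs, [("A", 2)], tol=5.0)) == 2

    def test_count_equals_tolerance_graph_oracle(self):
        """Well-separated groups: greedy leader clustering and all-pairs
        tolerance-graph components agree on <= 50 conformers."""
        import networkx as nx

        pairs = ([(-75, 150)] * 3 + [(-74, 151)] * 2 + [(-60, 150)] * 4
                 + [(-59, 149)] * 3 + [(-75, 135)] * 2 + [(-68, 143)] * 5)
        confs = self.conformers_at(pairs)
        clusters = cluster_conformers(confs, [("A", 2)], tol=5.0)

        feats = [geometry.conformer_features(c, [("A", 2)]) for c in confs]
        g = nx.Graph()
        g.add_nodes_from(range(len(confs)))
        for i in range(len(confs)):
            for j in range(i + 1, len(confs)):
                (ai, pi), (aj, pj) = feats[i], feats[j]
                if pi == pj and all(
                    abs(((x1 - x2 + 180) % 360) - 180) <= 5.0
                    for a1, a2 in zip(ai, aj) for x1, x2 in zip(a1, a2)
                ):
                    g.add_edge(i, j)
        assert len(clusters) == nx.number_connected_components(g)

    def test_pucker_partition(self):
        endo = TripleHelixModel({"A": build_chain("GPG", puckers={2: "endo"})})
        exo = TripleHelixModel({"A": build_chain("GPG", puckers={2: "exo"})})
        confs = [Conformer(endo, (), 0), Conformer(exo, (), 1)]
        clusters = cluster_conformers(confs, [("A", 2)])
        assert len(clusters) == 2
        assert {c.puckers for c in clusters} == {("endo",), ("exo",)}


class TestBackboneSpan:
    def test_extended_longer_than_compressed(self):
        # fully extended backbone vs the compressed coiled conformation
        assert backbone_span(9, phi=179.9, psi=179.9) > backbone_span(9, phi=-20.0, psi=120.0)

    def test_single_residue_equals_n_to_c_distance(self):
        res = build_chain("G")[0]
        expected = float(np.linalg.norm(res.atoms["C"] - res.atoms["N"]))
        assert backbone_span(1) == pytest.approx(expected)

    def test_approximately_linear_scaling(self):
        s10 = backbone_span(10, phi=-75.0, psi=150.0)
        s20 = backbone_span(20, phi=-75.0, psi=150.0)
        assert s20 / s10 == pytest.approx(2.0, rel=0.15)


class TestStructureIO:
    def test_round_trip_preserves_coordinates_to_pdb_precision(self, tmp_path, small_helix):
        model, _ = small_helix
        path = tmp_path / "helix.pdb"
        write_structure(model, path)
        back = read_structure(path)
        for key, coord in model.iter_atoms():
            assert np.allclose(back.atom(*key), coord, atol=1.5e-3)

    def test_parsed_residue_count(self, tmp_path):
        model, _ = synth.gen_triple_helix(synth.HelixConfig(n_triplets=12), seed=0)
        path = tmp_path / "h12.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.n_residues == 108  # 3 chains x 36 residues

    def test_missing_backbone_atom_raises(self, tmp_path, small_helix):
        model, _ = small_helix
        broken = model.copy()
        del broken.chains["A"][3].atoms["CA"]
        path = tmp_path / "broken.pdb"
        write_structure(broken, path)
        with pytest.raises(StructureError):
            read_structure(path)

    def test_wrong_chain_count_raises(self, tmp_path):
        model = TripleHelixModel({"A": build_chain("GPOGPO" if False else "GGGGGG")})
        path = tmp_path / "one_chain.pdb"
        write_structure(model, path)
        with pytest.raises(StructureError):
            read_structure(path)

    def test_hyp_recognised_by_od1(self, tmp_path):
        model, _ = synth.gen_triple_helix(synth.HelixConfig(n_triplets=4), seed=0)
        path = tmp_path / "h.pdb"
        write_structure(model, path)
        back = read_structure(path)
        names = {r.name for r in back.chains["A"]}
        assert "HYP" in names
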