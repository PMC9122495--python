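"""CG builder: protein mapping, elastic networks, bilayers, truncation."""

import numpy as np
import pytest

from seipincg.builder import (
    SphericalBilayerSpec,
    add_proteinized_pls,
    build_default_seipin_model,
    build_enm,
    build_flat_patch,
    build_interaction_table,
    build_spherical_bilayer,
    embed_protein,
    make_lipids,
    map_protein_cg,
    truncate_oligomer,
)
from seipincg.units import spring_kcal_to_internal


class TestMapProteinCG:
    def test_243_residues_to_61_beads(self):
        # Arg23-Arg265: 60 full 4-residue blocks plus a final block of 3
        rng = np.random.default_rng(0)
        res = rng.normal(size=(2, 243, 3))
        pos, sub, bonds, _, _ = map_protein_cg(res)
        assert len(pos) == 2 * 61
        assert (np.bincount(sub) == 61).all()

    def test_identical_positions_collapse(self):
        res = np.tile([[1.0, 2.0, 3.0]], (4, 1))[None]
        pos, _, _, _, _ = map_protein_cg(res)
        assert len(pos) == 1
        np.testing.assert_allclose(pos[0], [1.0, 2.0, 3.0])

    def test_line_blocks(self):
        res = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])[None]
        pos, _, bonds, _, r0 = map_protein_cg(res)
        np.testing.assert_allclose(pos[:, 0], [1.5, 5.5])
        assert len(bonds) == 1
        assert r0[0] == pytest.approx(4.0)

    def test_mass_weighting(self):
        res = np.array([[[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]]])
        pos, _, _, _, _ = map_protein_cg(res, residue_masses=[3.0, 1.0, 1.0, 1.0])
        assert pos[0, 0] == pytest.approx(1.0)

    def test_missing_residue_rejected(self):
        res = np.zeros((1, 8, 3))
        res[0, 5] = np.nan
        with pytest.raises(ValueError, match="residue 5"):
            map_protein_cg(res)


class TestENM:
    def test_two_beads_within_cutoff(self):
        net = build_enm(np.array([[0.0, 0, 0], [1.0, 0, 0]]), sc=0.2, cutoff=1.5)
        assert len(net) == 1
        assert net.r0[0] == pytest.approx(1.0)
        assert net.k[0] == pytest.approx(spring_kcal_to_internal(0.2))

    def test_two_beads_beyond_cutoff(self):
        net = build_enm(np.array([[0.0, 0, 0], [2.0, 0, 0]]), cutoff=1.5)
        assert len(net) == 0

    def test_collinear_chain_nearest_neighbours_only(self):
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        net = build_enm(pos, cutoff=1.5)
        assert len(net) == 4
        assert np.all(net.pairs[:, 1] - net.pairs[:, 0] == 1)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 4, (40, 3))
        net = build_enm(pos, cutoff=1.5)
        expect = {(i, j) for i in range(40) for j in range(i + 1, 40)
                  if np.linalg.norm(pos[i] - pos[j]) < 1.5}
        got = {tuple(sorted(p)) for p in net.pairs}
        assert got == expect

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            build_enm(np.zeros((2, 3)), sc=-1.0)


class TestDefaultModel:
    @pytest.fixture(scope="class")
    def model(self):
        return build_default_seipin_model(seed=0)

    def test_24_proteinized_pls(self, model):
        flag = model.topology.flag("proteinized_PL")
        mols = np.unique(model.topology.molecule_id[flag])
        assert len(mols) == 24

    def test_proteinized_pls_in_elastic_network(self, model):
        top = model.topology
        flag = top.flag("proteinized_PL")
        prot = top.bead_types == "PROT"
        linked = set()
        for i, j in top.springs:
            if flag[i] and prot[j]:
                linked.add(top.molecule_id[i])
            if flag[j] and prot[i]:
                linked.add(top.molecule_id[j])
        assert len(linked) == 24

    def test_proteinized_pls_oriented_like_lumenal_leaflet(self, model):
        top = model.topology
        heads = (top.bead_types == "PL_head") & top.flag("proteinized_PL")
        tails = (top.bead_types == "PL_tail") & top.flag("proteinized_PL")
        # heads toward the lumen (below the midplane), tails toward it
        assert model.positions[heads, 2].mean() < model.positions[tails, 2].mean()

    def test_request_zero_is_noop(self, model):
        before = model.topology.n_beads
        out = add_proteinized_pls(model, n_pl=0)
        assert out.topology.n_beads == before

    def test_reproducible_given_seed(self):
        a = build_default_seipin_model(seed=3)
        b = build_default_seipin_model(seed=3)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.topology.springs, b.topology.springs)


class TestTruncation:
    @pytest.fixture(scope="class")
    def model(self):
        return build_default_seipin_model(seed=1)

    def test_remove_six_leaves_five(self, model):
        out = truncate_oligomer(model, "remove_n_contiguous", 6)
        subs = np.unique(out.topology.subunit_id[out.topology.subunit_id >= 0])
        assert len(subs) == 5
        # remaining subunits are ring-contiguous
        assert sorted(subs) == list(range(6, 11))

    def test_remove_zero_unchanged(self, model):
        out = truncate_oligomer(model, "remove_n_contiguous", 0)
        assert out.topology.n_beads == model.topology.n_beads

    def test_lumenal_only_strips_tm(self, model):
        out = truncate_oligomer(model, "lumenal_only")
        assert out.topology.flag("tm_segment").sum() == 0
        assert out.topology.flag("TM_terminal_tip").sum() == 0
        # spring set is the induced subgraph: all endpoints survive
        assert out.topology.springs.max() < out.topology.n_beads

    def test_springs_incident_to_removed_deleted(self, model):
        out = truncate_oligomer(model, "remove_n_contiguous", 6)
        n = out.topology.n_beads
        assert np.all(out.topology.springs < n)

    def test_remove_all_rejected(self, model):
        with pytest.raises(ValueError):
            truncate_oligomer(model, "remove_n_contiguous", 11)


class TestInteractionTable:
    def test_defaults(self):
        t = build_interaction_table()
        assert t.factor("PROT", {"interfacial"}, "PL_interfacial", set()) == 1.5
        assert t.factor("PROT", {"hydrophobic_phase"}, "PL_tail", set()) == 1.0
        assert t.factor("PROT", {"TG_attractive_HH"}, "TG_tail", set()) == 1.5
        assert t.factor("PROT", {"TG_attractive_TM_core"}, "TG_glycerol", set()) == 1.5
        assert t.factor("PL_tail", set(), "PL_tail", set()) == 1.0
        assert t.factor("PROT", set(), "PL_head", set()) == 0.0

    def test_tip_scaling_parameter(self):
        t = build_interaction_table(tip_scaling_r=0.3)
        flags = {"TM_terminal_tip", "interfacial"}
        assert t.factor("PROT", flags, "PL_head", set()) == 0.3
        assert t.factor("PROT", flags, "PL_interfacial", set()) == 0.3

    def test_override_to_zero(self):
        t = build_interaction_table(overrides={("PL_tail", "PL_tail"): 0.0})
        assert t.factor("PL_tail", set(), "PL_tail", set()) == 0.0

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            build_interaction_table(overrides={("PL_tail", "PL_tail"): -1.0})

    def test_tg_attractive_beads_per_subunit(self):
        model = build_default_seipin_model(seed=0)
        top = model.topology
        for s in range(11):
            sub = top.subunit_id == s
            assert (top.flag("TG_attractive_HH") & sub).sum() == 2
            assert (top.flag("TG_attractive_TM_core") & sub).sum() == 8  # 4 per TM


class TestBilayers:
    def test_pure_pl_vesicle(self):
        spec = SphericalBilayerSpec(diameter=20.0, tg_percent=0.0)
        system = build_spherical_bilayer(spec, seed=0)
        assert not np.any(np.char.startswith(
            system.topology.bead_types.astype(str), "TG"))

    def test_tg_mole_fraction(self):
        spec = SphericalBilayerSpec(diameter=20.0, tg_percent=2.0)
        system = build_spherical_bilayer(spec, seed=0)
        top = system.topology
        n_tg = len(np.unique(top.molecule_id[top.bead_types == "TG_glycerol"]))
        n_pl = len(np.unique(top.molecule_id[top.bead_types == "PL_head"]))
        assert n_tg == round(0.02 / 0.98 * n_pl)
        assert n_tg / (n_tg + n_pl) == pytest.approx(0.02, abs=0.002)

    def test_leaflet_orientation(self):
        spec = SphericalBilayerSpec(diameter=20.0, tg_percent=0.0)
        system = build_spherical_bilayer(spec, seed=0)
        top = system.topology
        center = system.box / 2
        r = np.linalg.norm(system.positions - center, axis=1)
        heads = top.bead_types == "PL_head"
        tails = top.bead_types == "PL_tail"
        outer = r > (r.max() + r.min()) / 2  # midplane split of the leaflets
        # outer-leaflet heads sit outside every outer-leaflet tail bead
        assert r[heads & outer].min() > r[tails & outer].max()

    def test_reproducible(self):
        spec = SphericalBilayerSpec(diameter=20.0, tg_percent=2.0)
        a = build_spherical_bilayer(spec, seed=5)
        b = build_spherical_bilayer(spec, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SphericalBilayerSpec(diameter=-1.0)
        with pytest.raises(ValueError):
            SphericalBilayerSpec(tg_percent=100.0)


class TestEmbedding:
    def test_clash_removal_whole_molecules(self):
        from seipincg.demo import build_demo_cage

        patch = build_flat_patch(12.0, 12.0, 12.0, tg_percent=2.0, seed=0)
        cage = build_demo_cage(seed=0)
        combined = embed_protein(patch, cage, clash_cutoff=0.5)
        top = combined.topology
        n_before = len(np.unique(patch.topology.molecule_id))
        lipid = top.bead_types != "PROT"
        n_after = len(np.unique(top.molecule_id[lipid]))
        assert n_after < n_before
        # no remaining lipid bead within the cutoff of any protein bead
        from scipy.spatial import cKDTree

        tree = cKDTree(combined.positions[~lipid])
        d, _ = tree.query(combined.positions[lipid])
        assert d.min() >= 0.5
        # molecules removed whole: every lipid molecule keeps 4 beads
        _, counts = np.unique(top.molecule_id[lipid], return_counts=True)
        assert (counts == 4).all()

    def test_oversized_protein_rejected(self):
        from seipincg.demo import build_demo_cage

        patch = build_flat_patch(5.0, 5.0, 10.0, tg_percent=0.0, seed=0)
        cage = build_demo_cage(seed=0)
        with pytest.raises(ValueError):
            embed_protein(patch, cage)


class TestLipids:
    def test_pl_layout(self):
        top = make_lipids(["PL"])
        assert list(top.bead_types) == ["PL_head", "PL_interfacial",
                                        "PL_tail", "PL_tail"]
        assert len(top.bonds) == 3
        assert len(top.angles) == 2

    def test_tg_layout_no_angles(self):
        top = make_lipids(["TG"])
        assert list(top.bead_types) == ["TG_glycerol", "TG_tail",
                                        "TG_tail", "TG_tail"]
        assert len(top.angles) == 0

    def test_masses_and_charges(self):
        top = make_lipids(["PL", "TG"])
        assert np.all(top.masses == 200.0)
        assert np.all(top.charges == 0.0)
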