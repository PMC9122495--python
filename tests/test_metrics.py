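"""Lens morphology metrics: clustering, anisotropy, neck diameter, RMSF."""

import numpy as np
import pytest

from seipincg.metrics import (
    anisotropy,
    cluster_tg,
    metrics_timeseries,
    neck_diameter,
    nucleation_percentage,
    rmsf,
)
from seipincg.synth import gen_tg_cluster


def brute_force_labels(bead_pos, mol_ids, cutoff, box=None):
    """Independent O(n^2) union-find oracle for single-linkage clustering."""
    mols = np.unique(mol_ids)
    parent = {m: m for m in mols}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ai in range(len(bead_pos)):
        for bi in range(ai + 1, len(bead_pos)):
            if mol_ids[ai] == mol_ids[bi]:
                continue
            d = bead_pos[ai] - bead_pos[bi]
            if box is not None:
                d = d - box * np.round(d / box)
            if (d * d).sum() < cutoff * cutoff:
                ra, rb = find(mol_ids[ai]), find(mol_ids[bi])
                parent[ra] = rb
    return {m: find(m) for m in mols}


class TestClustering:
    def test_single_molecule(self):
        res = cluster_tg(np.zeros((4, 3)), [7] * 4)
        assert res.n_clusters == 1
        assert res.sizes[0] == 1

    def test_two_separated_molecules(self):
        pos = np.vstack([np.zeros((2, 3)), np.full((2, 3), 3.0)])
        res = cluster_tg(pos, [0, 0, 1, 1], cutoff=2.0)
        assert res.n_clusters == 2

    @pytest.mark.parametrize("use_box", [False, True])
    def test_oracle_equivalence_random_configs(self, use_box):
        rng = np.random.default_rng(11)
        box = np.array([8.0, 8.0, 8.0]) if use_box else None
        for _ in range(25):
            n_mol = rng.integers(2, 30)
            mols = np.repeat(np.arange(n_mol), 4)
            pos = rng.uniform(0, 8, (4 * n_mol, 3))
            res = cluster_tg(pos, mols, cutoff=2.0, box=box)
            oracle = brute_force_labels(pos, mols, 2.0, box)
            # same partition: equal labels iff same oracle root
            for a in range(n_mol):
                for b in range(a + 1, n_mol):
                    same = res.labels[a] == res.labels[b]
                    assert same == (oracle[a] == oracle[b])

    def test_no_tg_raises(self):
        with pytest.raises(ValueError):
            cluster_tg(np.zeros((0, 3)), [])


class TestNucleation:
    def test_all_in_one_cluster(self):
        res = cluster_tg(np.zeros((8, 3)), np.repeat([0, 1], 4))
        assert nucleation_percentage(res, 2) == pytest.approx(100.0)

    def test_two_singletons(self):
        pos = np.vstack([np.zeros((1, 3)), [[5.0, 0, 0]]])
        res = cluster_tg(pos, [0, 1], cutoff=2.0)
        assert nucleation_percentage(res, 2) == pytest.approx(50.0)

    def test_partition_sizes(self):
        # clusters of sizes 7, 2, 1 out of 10 -> 70%
        pos, mols = [], []
        for c, (size, x) in enumerate([(7, 0.0), (2, 50.0), (1, 100.0)]):
            for m in range(size):
                pos.append([x + 0.5 * m, 0, 0])
                mols.append(c * 10 + m)
        res = cluster_tg(np.array(pos), mols, cutoff=2.0)
        assert nucleation_percentage(res, 10) == pytest.approx(70.0)

    def test_merging_never_decreases_nucleation(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1.2, (10, 3))
        b = rng.uniform(0, 1.2, (6, 3)) + [10.0, 0, 0]
        mols = np.arange(16)
        far = cluster_tg(np.vstack([a, b]), mols, cutoff=2.0)
        near = cluster_tg(np.vstack([a, b - [8.5, 0, 0]]), mols, cutoff=2.0)
        assert nucleation_percentage(near, 16) >= nucleation_percentage(far, 16)


class TestAnisotropy:
    def test_sphere_limit(self):
        assert anisotropy(gen_tg_cluster("sphere", 10000, 3.0, seed=0)) < 0.01

    def test_disc_limit(self):
        disc = gen_tg_cluster("disc", 10000, 3.0, thickness=0.003, seed=0)
        assert anisotropy(disc) == pytest.approx(0.25, abs=0.01)

    def test_rod_limit(self):
        rod = gen_tg_cluster("rod", 10000, 10.0, thickness=0.005, seed=0)
        assert anisotropy(rod) > 0.95

    def test_line_exact(self):
        pts = np.column_stack([np.linspace(0, 5, 50), np.zeros(50), np.zeros(50)])
        assert anisotropy(pts) == pytest.approx(1.0)

    def test_bounds_random_clouds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pts = rng.normal(size=(30, 3)) * rng.uniform(0.1, 3, 3)
            assert 0.0 <= anisotropy(pts) <= 1.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 3)) * [3.0, 1.0, 0.3]
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + [10.0, -4.0, 2.0]
        assert anisotropy(moved) == pytest.approx(anisotropy(pts), rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            anisotropy(np.zeros((5, 3)))


class TestNeckDiameter:
    def test_exact_circle(self):
        ang = np.linspace(0, 2 * np.pi, 22, endpoint=False)
        tips = np.column_stack([7 * np.cos(ang), 7 * np.sin(ang), np.full(22, 2.0)])
        ring = np.vstack([tips, tips * [1, 1, -1]])  # symmetric ring for the axis
        assert neck_diameter(tips, ring) == pytest.approx(14.0)

    def test_two_concentric_circles(self):
        ang = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        c6 = np.column_stack([6 * np.cos(ang), 6 * np.sin(ang), np.zeros(10)])
        c8 = np.column_stack([8 * np.cos(ang), 8 * np.sin(ang), np.zeros(10)])
        assert neck_diameter(np.vstack([c6, c8])) == pytest.approx(14.0)

    def test_jittered_circle(self):
        rng = np.random.default_rng(42)
        ang = rng.uniform(0, 2 * np.pi, 50)
        tips = np.column_stack([7 * np.cos(ang), 7 * np.sin(ang), np.zeros(50)])
        tips += rng.normal(scale=0.1, size=tips.shape)
        assert neck_diameter(tips) == pytest.approx(14.0, abs=0.1)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            neck_diameter(np.zeros((2, 3)))


class TestRMSF:
    def test_rigid_ensemble_zero(self):
        ens = np.repeat(np.random.default_rng(0).normal(size=(1, 10, 3)), 5, axis=0)
        np.testing.assert_allclose(rmsf(ens), 0.0, atol=1e-12)

    def test_isotropic_gaussian(self):
        rng = np.random.default_rng(1)
        sigma = 0.05
        base = rng.normal(size=(1, 8, 3))
        ens = base + rng.normal(scale=sigma, size=(20000, 8, 3))
        np.testing.assert_allclose(rmsf(ens), sigma * np.sqrt(3), rtol=0.03)

    def test_henm_ensemble_matches_analytic(self):
        from seipincg.henm import model_rmsf
        from seipincg.synth import gen_gaussian_ensemble, gen_spring_truss

        pos, net = gen_spring_truss(12, seed=2)
        ens = gen_gaussian_ensemble(pos, net, 310.0, 8000, seed=3)
        analytic = model_rmsf(pos, net, 310.0)
        np.testing.assert_allclose(rmsf(ens), analytic, rtol=0.05)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            rmsf(np.zeros((1, 5, 3)))


class TestTimeseries:
    @staticmethod
    def _frames_from_series(series):
        """Frames of 2-molecule systems whose nucleation follows ``series``."""
        frames = []
        for nuc in series:
            # nuc is 50 (two singletons) or 100 (merged)
            gap = 1.0 if nuc == 100 else 5.0
            pos = np.array([[0, 0, 0.0], [gap, 0, 0]])
            frames.append((pos, np.array([0, 1])))
        return frames

    def test_coalescence_jump_tagged(self):
        frames = self._frames_from_series([50, 50, 50, 100, 100])
        df, tags = metrics_timeseries(frames, lambda f: (f[0], f[1], None))
        assert list(df["nucleation_percentage"]) == [50, 50, 50, 100, 100]
        assert tags.coalescence_frames == [3]

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 3, (12, 3))
        mols = np.repeat(np.arange(3), 4)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        res1 = cluster_tg(pos, mols, cutoff=2.0)
        res2 = cluster_tg(pos @ q.T + 5.0, mols, cutoff=2.0)
        assert np.array_equal(np.sort(res1.sizes), np.sort(res2.sizes))
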