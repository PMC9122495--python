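"""Langevin engine: potentials, forces, integration, neighbour search."""

import numpy as np
import pytest

from seipincg.builder import make_lipids
from seipincg.potentials import PairParams, pair_energy_force, tabulate
from seipincg.simulator import (
    ForceField,
    OverlapError,
    SimulationParams,
    candidate_pairs,
    compute_forces,
    run,
)
from seipincg.topology import CGSystem


def compact_system(n_lipids, box_l, seed=0):
    """Lipid molecules as compact chains on a lattice (no initial overlaps)."""
    rng = np.random.default_rng(seed)
    top = make_lipids(["PL"] * (n_lipids // 2) + ["TG"] * (n_lipids - n_lipids // 2))
    n_side = int(np.ceil(n_lipids ** (1 / 3)))
    pos = np.zeros((top.n_beads, 3))
    sp = box_l / n_side
    m = 0
    for a in range(n_side):
        for b in range(n_side):
            for c in range(n_side):
                if m >= n_lipids:
                    break
                anchor = (np.array([a, b, c]) + 0.3) * sp
                for k in range(4):
                    pos[4 * m + k] = anchor + [0.18 * k, 0.12 * k, 0.5 * k]
                m += 1
    return CGSystem(top, pos, np.full(3, float(box_l)))


class TestPairPotential:
    def test_zero_factor_purely_repulsive(self):
        r = np.linspace(0.3, 1.49, 400)
        e, _ = pair_energy_force(r, 0.0)
        assert e.min() >= 0.0

    def test_well_depth_scales_linearly(self):
        r = np.linspace(0.3, 1.49, 1000)
        e1, f1 = pair_energy_force(r, 1.0)
        e2, f2 = pair_energy_force(r, 2.0)
        assert e2.min() == pytest.approx(2 * e1.min())
        # the attractive (tail) force doubles too
        p = PairParams()
        tail = r > p.r_min
        np.testing.assert_allclose(f2[tail], 2 * f1[tail], rtol=1e-12)

    def test_smooth_zero_at_cutoff(self):
        p = PairParams()
        e, f = pair_energy_force(p.cutoff - 1e-9, 1.5, p)
        assert abs(e) < 1e-6
        assert abs(f) < 1e-4

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy_force(0.0, 1.0)

    def test_table_matches_closed_form(self):
        table = tabulate(1.5)
        e, f = pair_energy_force(table.r, 1.5)
        np.testing.assert_allclose(table.energy, e)
        np.testing.assert_allclose(table.force, f)
        # interpolation on a shifted grid reproduces the source function
        r_shift = table.r[:-1] + np.diff(table.r) / 3
        ei, fi = table.evaluate(r_shift)
        es, fs = pair_energy_force(r_shift, 1.5)
        scale = np.abs(es).max()
        assert np.max(np.abs(ei - es)) / scale < 1e-3
        assert np.max(np.abs(fi - fs)) / np.abs(fs).max() < 1e-3

    def test_table_force_consistent_with_energy(self):
        table = tabulate(1.0)
        assert table.check_consistency() < 1e-3
        assert table.energy[-1] == pytest.approx(0.0, abs=1e-12)


class TestForces:
    def test_finite_difference_match(self):
        # analytic gradient vs central differences on a random 50-bead system
        system = compact_system(12, 6.0, seed=1)  # 48 beads
        ff = ForceField.from_topology(system.topology)
        f, en = compute_forces(system.positions, system.box, system.topology, ff)
        rng = np.random.default_rng(2)
        h = 1e-5
        scale = np.abs(f).max()
        for _ in range(25):
            i = rng.integers(system.topology.n_beads)
            d = rng.integers(3)
            for sign, store in ((1, "p"), (-1, "m")):
                pos = system.positions.copy()
                pos[i, d] += sign * h
                _, e = compute_forces(pos, system.box, system.topology, ff)
                if sign == 1:
                    ep = e["potential"]
                else:
                    em = e["potential"]
            fd = -(ep - em) / (2 * h)
            assert abs(fd - f[i, d]) / scale < 1e-6

    def test_newton_third_law(self):
        system = compact_system(8, 5.0, seed=3)
        ff = ForceField.from_topology(system.topology)
        f, _ = compute_forces(system.positions, system.box, system.topology, ff)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_bond_at_rest_length_no_force(self):
        top = make_lipids(["TG"])
        pos = np.array([[0.0, 0, 0], [0.75, 0, 0], [1.5, 0, 0], [2.25, 0, 0]])
        system = CGSystem(top, pos + 5.0, np.full(3, 10.0))
        ff = ForceField.from_topology(top)
        # beads are colinear at the bond rest length; 1-2/1-3 are excluded,
        # only the 1-4 nonbonded pair acts — subtract it by zeroing factors
        ff.factor_matrix[:] = 0.0
        f, en = compute_forces(system.positions, system.box, top, ff)
        assert en["bond"] == pytest.approx(0.0, abs=1e-12)
        # 1-4 WCA at 2.25 nm is beyond cutoff range of the repulsive core
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_overlap_detected(self):
        top = make_lipids(["PL", "PL"])
        pos = np.zeros((8, 3))
        pos[0] = [1.0, 1.0, 1.0]
        pos[4] = [1.0, 1.0, 1.001]  # two beads of different molecules overlap
        pos[1:4] = [[3, 3, 3], [4, 4, 4], [5, 5, 5]]
        pos[5:8] = [[6, 6, 6], [7, 7, 7], [8, 8, 8]]
        system = CGSystem(top, pos, np.full(3, 10.0))
        ff = ForceField.from_topology(top)
        with pytest.raises(OverlapError):
            compute_forces(system.positions, system.box, top, ff)

    def test_tree_pairs_match_all_pairs(self):
        rng = np.random.default_rng(4)
        system = compact_system(20, 7.0, seed=5)
        ff = ForceField.from_topology(system.topology)
        for _ in range(3):
            pos = system.positions + rng.normal(scale=0.5, size=(1, 3))
            t = candidate_pairs(pos, system.box, 1.5, ff, method="tree")
            a = candidate_pairs(pos, system.box, 1.5, ff, method="all")
            assert set(zip(*map(list, t))) == set(zip(*map(list, a)))


class TestIntegration:
    def test_nve_energy_conservation(self):
        # thermalise, then integrate without friction/noise at reduced dt
        system = compact_system(25, 5.0, seed=1)  # 100 beads
        ff = ForceField.from_topology(system.topology)
        eq = run(system, ff, SimulationParams(dt=0.02, damping=1.0,
                                              n_steps=2000, seed=3),
                 traj_stride=10 ** 9, log_stride=2000)
        sys2 = CGSystem(system.topology, eq.final_state.positions, system.box)
        res = run(sys2, ff, SimulationParams(dt=0.005, damping=None,
                                             n_steps=10000, seed=4),
                  traj_stride=10 ** 9, log_stride=100)
        e_tot = res.log["potential"] + res.log["kinetic"]
        assert (e_tot.max() - e_tot.min()) / abs(e_tot[0]) < 1e-4

    def test_thermostat_reaches_target(self):
        # short sanity run; the long statistical check lives in acceptance
        # tight coupling so the stressed start thermalises quickly; the
        # production-coupling statistical check lives in the acceptance suite
        system = compact_system(25, 5.0, seed=2)
        ff = ForceField.from_topology(system.topology)
        res = run(system, ff, SimulationParams(dt=0.05, damping=5.0,
                                               n_steps=10000, seed=5),
                  traj_stride=10 ** 9, log_stride=200)
        temps = res.log["temperature"][25:]
        assert temps.mean() == pytest.approx(310.0, rel=0.05)

    def test_bit_identical_given_seed(self):
        system = compact_system(10, 5.0, seed=6)
        ff = ForceField.from_topology(system.topology)
        params = SimulationParams(dt=0.02, n_steps=200, seed=9)
        a = run(system, ff, params, traj_stride=50, log_stride=100)
        b = run(system, ff, params, traj_stride=50, log_stride=100)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.final_state.velocities,
                                      b.final_state.velocities)

    def test_frozen_beads_do_not_move(self):
        system = compact_system(10, 5.0, seed=7)
        ff = ForceField.from_topology(system.topology)
        mobile = np.ones(system.topology.n_beads, dtype=bool)
        mobile[:4] = False
        res = run(system, ff, SimulationParams(dt=0.02, n_steps=100, seed=1),
                  traj_stride=100, log_stride=100, mobile=mobile)
        np.testing.assert_array_equal(res.positions[-1][:4],
                                      system.positions[:4])

    def test_checkpoint_resume_continuous(self):
        system = compact_system(10, 5.0, seed=8)
        ff = ForceField.from_topology(system.topology)
        full = run(system, ff, SimulationParams(dt=0.02, n_steps=200, seed=2),
                   traj_stride=100, log_stride=200)
        half = run(system, ff, SimulationParams(dt=0.02, n_steps=100, seed=2),
                   traj_stride=100, log_stride=200)
        rest = run(CGSystem(system.topology, half.final_state.positions,
                            system.box),
                   ff, SimulationParams(dt=0.02, n_steps=100, seed=2),
                   traj_stride=100, log_stride=200, state=half.final_state)
        np.testing.assert_allclose(rest.positions[-1], full.positions[-1],
                                   atol=1e-12)
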