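"""Desk-scale Langevin dynamics engine for the CG model.

Underdamped Langevin dynamics with a velocity-Verlet core and BAOAB
splitting: friction gamma = m / damping-time and Gaussian noise satisfying
fluctuation-dissipation at the target temperature (310 K, coupling constant
100 ps and a 50 fs time step in the production setup).  With the thermostat
disabled the integrator reduces to plain velocity Verlet and conserves
energy.  Nonbonded forces use the scaled pair family of
:mod:`seipincg.potentials` over a Verlet neighbour list built from a
periodic k-d tree; bonded terms are harmonic bonds/springs k (r - r0)^2 and
harmonic angles k (theta - theta0)^2.

The noise stream is a counter-based generator keyed by (seed, step) with
draws in bead order, so trajectories are bit-identical for identical seeds
on the same platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .potentials import PairParams
from .topology import CGSystem, CGTopology, InteractionTable, build_interaction_table
from .units import KB

__all__ = [
    "SimulationParams",
    "ForceField",
    "candidate_pairs",
    "NeighborList",
    "compute_forces",
    "langevin_step",
    "run",
    "SimulationState",
    "SimulationResult",
    "kinetic_temperature",
]

#: below this separation (nm) the potential-table range is exceeded
MIN_PAIR_DISTANCE = 0.05


@dataclass
class SimulationParams:
    """Integration parameters (defaults follow the production CG protocol)."""

    dt: float = 0.05  # ps (50 fs)
    temperature: float = 310.0  # K
    damping: float | None = 100.0  # ps Langevin coupling; None = NVE
    cutoff: float = 1.5  # nm nonbonded cutoff
    seed: int = 0
    n_steps: int = 1000
    skin: float = 0.3  # nm neighbour-list skin

    def __post_init__(self):
        if self.dt <= 0 or self.cutoff <= 0:
            raise ValueError("dt and cutoff must be positive")


# --- force field --------------------------------------------------------------

@dataclass
class ForceField:
    """Pair parameters and per-bead interaction classes resolved on a topology."""

    pair_params: PairParams
    class_id: np.ndarray  # (N,) int
    factor_matrix: np.ndarray  # (n_class, n_class)
    exclusion_keys: np.ndarray  # sorted int64 keys i*N+j, i<j
    n_beads: int

    @classmethod
    def from_topology(cls, topology: CGTopology,
                      table: InteractionTable | None = None,
                      pair_params: PairParams | None = None) -> "ForceField":
        if table is None:
            table = build_interaction_table()
        if pair_params is None:
            pair_params = PairParams()
        descr = [(topology.bead_types[i], topology.bead_flags(i))
                 for i in range(topology.n_beads)]
        uniq = sorted({(t, tuple(sorted(f))) for t, f in descr})
        index = {u: c for c, u in enumerate(uniq)}
        class_id = np.array([index[(t, tuple(sorted(f)))] for t, f in descr],
                            dtype=np.int64)
        n_class = len(uniq)
        fmat = np.zeros((n_class, n_class))
        for (ta, fa), ca in index.items():
            for (tb, fb), cb in index.items():
                fmat[ca, cb] = table.factor(ta, fa, tb, fb)
        excl = _exclusion_keys(topology)
        return cls(pair_params, class_id, fmat, excl, topology.n_beads)


def _exclusion_keys(topology: CGTopology) -> np.ndarray:
    """Nonbonded exclusions: bonded 1-2, angle 1-3, and spring pairs."""
    n = topology.n_beads
    pairs = [topology.bonds, topology.springs]
    if len(topology.angles):
        pairs.append(topology.angles[:, [0, 2]])
    allp = np.vstack([p for p in pairs if len(p)]) if any(len(p) for p in pairs) \
        else np.zeros((0, 2), dtype=int)
    if not len(allp):
        return np.zeros(0, dtype=np.int64)
    lo = allp.min(axis=1).astype(np.int64)
    hi = allp.max(axis=1).astype(np.int64)
    return np.unique(lo * n + hi)


def candidate_pairs(positions, box, cutoff, ff: ForceField | None = None,
                    method: str = "tree") -> tuple[np.ndarray, np.ndarray]:
    """Bead pairs within ``cutoff`` (minimum image), exclusions removed.

    ``method='tree'`` uses a periodic k-d tree; ``method='all'`` enumerates
    all pairs and filters — the reference path the tree is validated against.
    """
    pos = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    n = len(pos)
    if method == "tree":
        wrapped = np.mod(pos, box)
        # floating-point mod can land exactly on the upper box edge
        wrapped[wrapped >= box] = 0.0
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
    elif method == "all":
        iu, ju = np.triu_indices(n, k=1)
        d = pos[iu] - pos[ju]
        d -= box * np.round(d / box)
        keep = (d * d).sum(axis=1) < cutoff * cutoff
        pairs = np.column_stack([iu[keep], ju[keep]])
    else:
        raise ValueError(f"unknown pair method {method!r}")
    if len(pairs) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    lo = pairs.min(axis=1).astype(np.int64)
    hi = pairs.max(axis=1).astype(np.int64)
    excl = ff.exclusion_keys if ff is not None else None
    if excl is not None and len(excl):
        keys = lo * n + hi
        idx = np.searchsorted(excl, keys)
        idx[idx == len(excl)] = 0
        keep = excl[idx] != keys
        lo, hi = lo[keep], hi[keep]
    return lo, hi


class NeighborList:
    """Verlet list with a skin; rebuilt when any bead moves further than skin/2."""

    def __init__(self, ff: ForceField, params: SimulationParams):
        self.ff = ff
        self.cutoff = params.cutoff
        self.skin = params.skin
        self._ref = None
        self.pairs = None

    def update(self, positions, box, force_rebuild=False):
        if self._ref is not None and not force_rebuild:
            disp = np.abs(positions - self._ref).max()
            if disp < self.skin / 2:
                return self.pairs
        self._ref = positions.copy()
        self.pairs = candidate_pairs(positions, box, self.cutoff + self.skin, self.ff)
        return self.pairs


# --- forces -------------------------------------------------------------------

@njit(cache=True)
def _nonbonded_kernel(pos, box, pi, pj, class_id, fmat, sigma, eps_rep,
                      eps_att, rc, min_r, forces):
    energy = 0.0
    bad_i, bad_j = -1, -1
    rm = 2.0 ** (1.0 / 6.0) * sigma
    w = rc - rm
    rc2 = rc * rc
    for n in range(len(pi)):
        i = pi[n]
        j = pj[n]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        if r < min_r:
            bad_i, bad_j = i, j
            break
        ea = fmat[class_id[i], class_id[j]] * eps_att
        if r < rm:
            sr6 = (sigma / r) ** 6
            e = 4.0 * eps_rep * (sr6 * sr6 - sr6) + eps_rep - ea
            fmag = 4.0 * eps_rep * (12.0 * sr6 * sr6 - 6.0 * sr6) / r
        else:
            x = np.pi * (r - rm) / (2.0 * w)
            c = np.cos(x)
            e = -ea * c * c
            fmag = -ea * np.pi / (2.0 * w) * np.sin(2.0 * x)
        energy += e
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, bad_i, bad_j


def _harmonic_pair_forces(pos, box, pairs, k, r0, forces):
    """Bond/spring terms k (r - r0)^2; returns their total energy."""
    if not len(pairs):
        return 0.0
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    dr = r - r0
    fmag = -2.0 * k * dr / r
    fvec = fmag[:, None] * d
    np.add.at(forces, pairs[:, 0], fvec)
    np.add.at(forces, pairs[:, 1], -fvec)
    return float(np.sum(k * dr * dr))


def _angle_forces(pos, box, angles, k, theta0, forces):
    """Harmonic angles k (theta - theta0)^2; returns their total energy."""
    if not len(angles):
        return 0.0
    i, j, m = angles[:, 0], angles[:, 1], angles[:, 2]
    rij = pos[i] - pos[j]
    rij -= box * np.round(rij / box)
    rmj = pos[m] - pos[j]
    rmj -= box * np.round(rmj / box)
    li = np.linalg.norm(rij, axis=1)
    lm = np.linalg.norm(rmj, axis=1)
    cos_t = np.clip(np.einsum("ni,ni->n", rij, rmj) / (li * lm), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t ** 2, 1e-16))
    dEdt = 2.0 * k * (theta - theta0)
    coef = dEdt / sin_t
    dcos_di = rmj / (li * lm)[:, None] - cos_t[:, None] * rij / (li ** 2)[:, None]
    dcos_dm = rij / (li * lm)[:, None] - cos_t[:, None] * rmj / (lm ** 2)[:, None]
    fi = coef[:, None] * dcos_di
    fm = coef[:, None] * dcos_dm
    np.add.at(forces, i, fi)
    np.add.at(forces, m, fm)
    np.add.at(forces, j, -(fi + fm))
    return float(np.sum(k * (theta - theta0) ** 2))


class OverlapError(RuntimeError):
    def __init__(self, i, j):
        self.pair = (i, j)
        super().__init__(f"beads {i} and {j} closer than the table range "
                         f"({MIN_PAIR_DISTANCE} nm)")


def compute_forces(positions, box, topology: CGTopology, ff: ForceField,
                   pairs=None):
    """Total forces (kJ/mol/nm) and an energy breakdown (kJ/mol).

    ``pairs`` is an optional precomputed (i, j) candidate-pair tuple (e.g.
    from a :class:`NeighborList`); all pairs within the cutoff are used
    otherwise.  Pairwise forces obey Newton's third law by construction.
    """
    pos = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    forces = np.zeros_like(pos)
    if pairs is None:
        pairs = candidate_pairs(pos, box, ff.pair_params.cutoff, ff)
    pp = ff.pair_params
    e_nb, bad_i, bad_j = _nonbonded_kernel(
        pos, box, pairs[0], pairs[1], ff.class_id, ff.factor_matrix,
        pp.sigma, pp.eps_rep, pp.eps_att, pp.cutoff, MIN_PAIR_DISTANCE, forces)
    if bad_i >= 0:
        raise OverlapError(bad_i, bad_j)
    e_bond = _harmonic_pair_forces(pos, box, topology.bonds, topology.bond_k,
                                   topology.bond_r0, forces)
    e_spring = _harmonic_pair_forces(pos, box, topology.springs,
                                     topology.spring_k, topology.spring_r0, forces)
    e_angle = _angle_forces(pos, box, topology.angles, topology.angle_k,
                            topology.angle_theta0, forces)
    energies = {"nonbonded": e_nb, "bond": e_bond, "spring": e_spring,
                "angle": e_angle,
                "potential": e_nb + e_bond + e_spring + e_angle}
    return forces, energies


# --- integration --------------------------------------------------------------

@dataclass
class SimulationState:
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    step: int = 0


def _noise(seed: int, step: int, shape) -> np.ndarray:
    rng = np.random.Generator(np.random.Philox(key=[seed, step]))
    return rng.standard_normal(shape)


def kinetic_temperature(velocities, masses, mobile=None) -> float:
    """Instantaneous kinetic temperature, K."""
    v = velocities if mobile is None else velocities[mobile]
    m = masses if mobile is None else masses[mobile]
    ke = 0.5 * float(np.sum(m[:, None] * v * v))
    return 2.0 * ke / (3.0 * len(v) * KB)


def langevin_step(state: SimulationState, system: CGSystem, ff: ForceField,
                  params: SimulationParams, nlist: NeighborList | None = None,
                  mobile=None) -> SimulationState:
    """One BAOAB step (velocity Verlet when ``params.damping`` is None).

    Friction is mass / damping-time per bead with matched Gaussian noise at
    the target temperature; deterministic given ``params.seed`` and the step
    counter.  ``mobile`` is an optional boolean mask — beads outside it are
    frozen in place.
    """
    dt = params.dt
    m = system.topology.masses[:, None]
    pos = state.positions
    vel = state.velocities.copy()
    if mobile is None:
        mobile = np.ones(len(pos), dtype=bool)

    vel[mobile] += 0.5 * dt * state.forces[mobile] / m[mobile]
    newpos = pos.copy()
    newpos[mobile] += 0.5 * dt * vel[mobile]
    if params.damping is not None:
        c1 = np.exp(-dt / params.damping)
        c2 = np.sqrt((1.0 - c1 * c1) * KB * params.temperature / m[mobile, 0])
        xi = _noise(params.seed, state.step, (len(pos), 3))[mobile]
        vel[mobile] = c1 * vel[mobile] + c2[:, None] * xi
    newpos[mobile] += 0.5 * dt * vel[mobile]
    if not np.all(np.isfinite(newpos)):
        raise RuntimeError(f"non-finite positions at step {state.step} (blow-up)")
    pairs = nlist.update(newpos, system.box) if nlist is not None else None
    forces, _ = compute_forces(newpos, system.box, system.topology, ff, pairs)
    vel[mobile] += 0.5 * dt * forces[mobile] / m[mobile]
    return SimulationState(newpos, vel, forces, state.step + 1)


@dataclass
class SimulationResult:
    """Saved frames and per-log-step observables of one run."""

    positions: np.ndarray  # (n_saved, N, 3), unwrapped nm
    steps: np.ndarray  # (n_saved,)
    log: dict = field(default_factory=dict)  # name -> array over log points
    final_state: SimulationState = None


def run(system: CGSystem, ff: ForceField | None = None,
        params: SimulationParams = SimulationParams(),
        traj_stride: int = 100, log_stride: int = 100,
        mobile=None, state: SimulationState | None = None,
        observers=None) -> SimulationResult:
    """Integrate ``params.n_steps`` steps, saving frames and a log.

    Velocities are initialised from the Maxwell-Boltzmann distribution at
    the target temperature unless a ``state`` (checkpoint) is resumed.
    ``observers`` is an optional list of callables ``f(state) -> (name,
    value)`` sampled at the log stride.
    """
    if ff is None:
        ff = ForceField.from_topology(system.topology)
    nlist = NeighborList(ff, params)
    masses = system.topology.masses
    if state is None:
        rng = np.random.Generator(np.random.Philox(key=[params.seed, 2 ** 31]))
        vel = rng.standard_normal((len(system.positions), 3)) \
            * np.sqrt(KB * params.temperature / masses)[:, None]
        if mobile is not None:
            vel[~np.asarray(mobile, dtype=bool)] = 0.0
        pairs = nlist.update(system.positions, system.box, force_rebuild=True)
        forces, _ = compute_forces(system.positions, system.box,
                                   system.topology, ff, pairs)
        state = SimulationState(system.positions.copy(), vel, forces, 0)

    frames, steps, log = [], [], {"step": [], "temperature": [], "potential": [],
                                  "kinetic": []}
    for _ in range(params.n_steps):
        state = langevin_step(state, system, ff, params, nlist, mobile)
        if state.step % traj_stride == 0:
            frames.append(state.positions.copy())
            steps.append(state.step)
        if state.step % log_stride == 0:
            pairs = nlist.update(state.positions, system.box)
            _, en = compute_forces(state.positions, system.box,
                                   system.topology, ff, pairs)
            ke = 0.5 * float(np.sum(masses[:, None] * state.velocities ** 2))
            log["step"].append(state.step)
            log["temperature"].append(
                kinetic_temperature(state.velocities, masses, mobile))
            log["potential"].append(en["potential"])
            log["kinetic"].append(ke)
            if observers:
                for obs in observers:
                    name, value = obs(state)
                    log.setdefault(name, []).append(value)
    return SimulationResult(
        np.array(frames) if frames else np.zeros((0, len(system.positions), 3)),
        np.array(steps, dtype=int),
        {k: np.array(v) for k, v in log.items()},
        state,
    )


def equilibrated_run(system: CGSystem, ff: ForceField | None = None,
                     params: SimulationParams = SimulationParams(),
                     warmup_steps: int = 3000, warmup_dt: float = 0.005,
                     warmup_damping: float = 1.0, **run_kwargs) -> SimulationResult:
    """Short tightly-coupled small-time-step warmup, then the production run.

    Freshly built configurations carry packing stress that the production
    time step cannot absorb; the warmup relaxes them at reduced dt with a
    fast thermostat before handing over to ``params``.
    """
    if ff is None:
        ff = ForceField.from_topology(system.topology)
    mobile = run_kwargs.get("mobile")
    warm = run(system, ff,
               SimulationParams(dt=warmup_dt, temperature=params.temperature,
                                damping=warmup_damping, cutoff=params.cutoff,
                                seed=params.seed + 1, n_steps=warmup_steps,
                                skin=params.skin),
               traj_stride=2 ** 62, log_stride=2 ** 62, mobile=mobile)
    eq = CGSystem(system.topology, warm.final_state.positions, system.box)
    return run(eq, ff, params, **run_kwargs)
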