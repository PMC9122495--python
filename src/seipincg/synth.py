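"""Synthetic fixtures with the statistical structure the analyses assume.

The study's molecular-dynamics trajectories are large and external; every
analysis stage in this package is instead exercised against generated data
whose ground truth is known exactly: flat bilayer patches at reduced
resolution with a controlled TG fraction, TG clusters of controlled shape
(sphere / disc / rod), planar Brownian walkers with class-dependent
diffusion coefficients (optionally confined in a harmonic trap), thermal
ensembles drawn from a known spring network, and an idealized ring-shaped
seipin cage (11 subunits, each with a lumenal blob, a hydrophobic-helix arc
and two membrane-spanning TM segments with annotated attraction sites).

Every generator is deterministic per seed and returns its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .henm import SpringNetwork, sample_gaussian_ensemble
from .mapping import GroupedFrame, build_default_schemes

__all__ = [
    "ProteinGeometry",
    "BrownianTrajectory",
    "gen_bilayer_patch",
    "gen_tg_cluster",
    "gen_brownian",
    "gen_gaussian_ensemble",
    "gen_idealized_seipin",
]


# --- idealized seipin cage ----------------------------------------------------

@dataclass
class ProteinGeometry:
    """Bead-resolution idealized seipin cage with annotation flags."""

    positions: np.ndarray  # (N, 3) nm; membrane midplane z=0, cytosol +z
    subunit_id: np.ndarray  # (N,) int
    flags: dict  # flag name -> (N,) bool
    hh_ring_radius: float
    tm_ring_radius: float
    membrane_half_thickness: float

    @property
    def n_beads(self) -> int:
        return len(self.positions)


def gen_idealized_seipin(
    ring_radius: float = 4.5,
    n_subunits: int = 11,
    beads_per_subunit: int = 61,
    hh_ring_radius: float = 2.0,
    tm_ring_radius: float = 6.5,
    tm_length: float = 4.5,
    n_tm_beads: int = 7,
    n_hh_beads: int = 4,
    membrane_half_thickness: float = 2.25,
    jitter: float = 0.02,
    seed: int = 0,
) -> ProteinGeometry:
    """Idealized undecamer cage standing in for the structural seipin model.

    Per subunit: a lumenal-domain blob below the membrane at ``ring_radius``,
    an HH arc at lumenal-leaflet depth on a ring of radius ~2 nm carrying two
    TG-attractive beads, and two TM segments spanning the membrane at
    ``tm_ring_radius`` whose four central beads attract TG and whose
    cytosolic terminal bead is a flagged tip at the membrane surface.  The
    cage is C_n symmetric up to the (small) placement jitter.
    """
    if n_subunits < 1:
        raise ValueError("need at least one subunit")
    if n_tm_beads < 6:
        raise ValueError("TM segments need >= 6 beads (4 central + 2 ends)")
    n_lum = beads_per_subunit - 2 * n_tm_beads - n_hh_beads
    if n_lum < 1:
        raise ValueError("beads_per_subunit too small for the TM/HH layout")
    rng = np.random.default_rng(seed)
    h = membrane_half_thickness

    sub_pos, sub_flags = [], {f: [] for f in (
        "hydrophobic_phase", "interfacial", "TG_attractive_HH",
        "TG_attractive_TM_core", "TM_terminal_tip", "tm_segment", "hh",
        "lumenal_domain")}

    def add(xyz, **flags):
        sub_pos.append(xyz)
        for f in sub_flags:
            sub_flags[f].append(bool(flags.get(f, False)))

    # lumenal blob: compact grid below the membrane
    n_side = int(np.ceil(n_lum ** (1 / 3)))
    grid = []
    for a in range(n_side):
        for b in range(n_side):
            for c in range(n_side):
                grid.append((a, b, c))
    grid = np.array(grid[:n_lum], dtype=float) * 0.8
    grid -= grid.mean(axis=0)
    for g in grid:
        add(np.array([ring_radius + g[0], g[1], -h - 1.6 + g[2]]),
            lumenal_domain=True)

    # HH arc at lumenal-leaflet depth; two beads flagged TG-attractive
    arc_span = 2 * np.pi / max(n_subunits, 2) * 0.8
    arc = np.linspace(-arc_span / 2, arc_span / 2, n_hh_beads)
    hh_z = -h * 0.62
    hh_att = {n_hh_beads // 2 - 1, n_hh_beads // 2}
    for bi, a in enumerate(arc):
        add(np.array([hh_ring_radius * np.cos(a), hh_ring_radius * np.sin(a), hh_z]),
            hh=True, lumenal_domain=True, hydrophobic_phase=True,
            TG_attractive_HH=bi in hh_att)

    # two TM segments spanning the membrane
    z = np.linspace(-tm_length / 2, tm_length / 2, n_tm_beads)
    central = set(range((n_tm_beads - 4) // 2, (n_tm_beads - 4) // 2 + 4))
    for seg, ang_off in ((0, -0.12), (1, 0.12)):
        for bi, zz in enumerate(z):
            interfacial = abs(abs(zz) - h) < 0.6
            add(np.array([tm_ring_radius * np.cos(ang_off),
                          tm_ring_radius * np.sin(ang_off), zz]),
                tm_segment=True,
                hydrophobic_phase=abs(zz) < h - 0.6,
                interfacial=interfacial,
                TG_attractive_TM_core=bi in central,
                TM_terminal_tip=bi == n_tm_beads - 1)

    sub_pos = np.array(sub_pos)
    positions, subunit_id = [], []
    flags = {f: [] for f in sub_flags}
    for s in range(n_subunits):
        ang = 2 * np.pi * s / n_subunits
        c, sn = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
        pos = sub_pos @ rot.T + rng.normal(scale=jitter, size=sub_pos.shape)
        positions.append(pos)
        subunit_id.extend([s] * len(sub_pos))
        for f in flags:
            flags[f].extend(sub_flags[f])
    return ProteinGeometry(
        positions=np.vstack(positions),
        subunit_id=np.array(subunit_id, dtype=int),
        flags={f: np.array(v, dtype=bool) for f, v in flags.items()},
        hh_ring_radius=hh_ring_radius,
        tm_ring_radius=tm_ring_radius,
        membrane_half_thickness=membrane_half_thickness,
    )


# --- TG clusters of controlled shape -----------------------------------------

def gen_tg_cluster(shape: str, n: int, size: float, thickness: float = 0.0,
                   seed: int = 0) -> np.ndarray:
    """Uniform points inside a sphere, thin disc, or rod.

    ``size`` is the sphere/disc radius or rod length (nm); ``thickness`` the
    disc thickness or rod radius.  Deterministic per seed.
    """
    if n < 4:
        raise ValueError("need n >= 4 points")
    rng = np.random.default_rng(seed)
    if shape == "sphere":
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = size * rng.random(n) ** (1 / 3)
        return v * r[:, None]
    if shape == "disc":
        ang = rng.random(n) * 2 * np.pi
        r = size * np.sqrt(rng.random(n))
        z = (rng.random(n) - 0.5) * thickness
        return np.column_stack([r * np.cos(ang), r * np.sin(ang), z])
    if shape == "rod":
        x = (rng.random(n) - 0.5) * size
        ang = rng.random(n) * 2 * np.pi
        r = thickness * np.sqrt(rng.random(n))
        return np.column_stack([x, r * np.cos(ang), r * np.sin(ang)])
    raise ValueError(f"unknown shape {shape!r}")


# --- Brownian walkers ---------------------------------------------------------

@dataclass
class BrownianTrajectory:
    """Planar random-walk trajectory with embedded ground truth."""

    positions: np.ndarray  # (n_frames, n_walkers, 3); z = 0
    dt: float  # us per frame
    D: np.ndarray  # (n_walkers,) ground-truth D, nm^2/us
    labels: np.ndarray  # (n_walkers,) class label per walker
    trap_rate: float | None = None  # 1/us, if confined


def gen_brownian(
    n_walkers: int = None,
    D: float = 1.0,
    n_frames: int = 1000,
    dt: float = 1e-3,
    classes: dict | None = None,
    confinement: float | None = None,
    start_radius: float = 0.0,
    seed: int = 0,
) -> BrownianTrajectory:
    """Independent 2D Brownian walkers with known diffusion coefficients.

    Either pass ``n_walkers``+``D`` for a single class, or ``classes`` as a
    mapping label -> (n_walkers, D, mean_radius); walkers of each class start
    on a circle of that radius.  Increments are Gaussian with per-axis
    variance 2 D dt.  ``confinement`` (trap relaxation rate, 1/us) switches
    to an exact Ornstein-Uhlenbeck update about the start position, whose
    MSD plateaus at 4 D / rate.
    """
    rng = np.random.default_rng(seed)
    if classes is None:
        if n_walkers is None:
            raise ValueError("pass n_walkers or classes")
        classes = {"all": (n_walkers, D, start_radius)}
    Ds, labels, starts = [], [], []
    for label, (n, d, radius) in classes.items():
        if d < 0:
            raise ValueError("D must be non-negative")
        ang = rng.random(n) * 2 * np.pi
        starts.append(np.column_stack([radius * np.cos(ang), radius * np.sin(ang)]))
        Ds.extend([d] * n)
        labels.extend([label] * n)
    start = np.vstack(starts)
    Ds = np.array(Ds)
    nw = len(Ds)

    pos = np.empty((n_frames, nw, 2))
    pos[0] = start
    sig_free = np.sqrt(2 * Ds * dt)
    if confinement is None:
        steps = rng.standard_normal((n_frames - 1, nw, 2)) * sig_free[None, :, None]
        pos[1:] = start[None] + np.cumsum(steps, axis=0)
    else:
        k = float(confinement)
        decay = np.exp(-k * dt)
        sig_ou = np.sqrt(Ds / k * (1 - decay ** 2)) if k > 0 else sig_free
        for t in range(1, n_frames):
            noise = rng.standard_normal((nw, 2))
            pos[t] = start + (pos[t - 1] - start) * decay + noise * sig_ou[:, None]
    out = np.zeros((n_frames, nw, 3))
    out[:, :, :2] = pos
    return BrownianTrajectory(out, dt, Ds, np.array(labels, dtype=object),
                              confinement)


# --- Gaussian ensembles from a known spring network ---------------------------

def gen_gaussian_ensemble(positions, network: SpringNetwork, temperature: float = 310.0,
                          n_samples: int = 5000, seed: int = 0) -> np.ndarray:
    """Thermal ensemble of a harmonic spring network via its normal modes.

    Samples are drawn from the exact equilibrium Gaussian of the linearised
    network at ``temperature`` (rigid-body modes removed, so the ensemble is
    already aligned); the sample covariance converges to the analytic one.
    Disconnected networks (internal zero modes) are rejected.
    """
    rng = np.random.default_rng(seed)
    return sample_gaussian_ensemble(positions, network, temperature, n_samples, rng)


def gen_spring_truss(n_beads: int = 20, k_range=(300.0, 900.0), seed: int = 0,
                     radius: float = 0.45, twist: float = 2.3, rise: float = 0.3):
    """Statically determinate spring truss for fluctuation-matching tests.

    Beads sit on a helix and each bead is connected to its three
    predecessors (a chain of stacked tetrahedra), giving exactly 3N-6
    springs: the minimally rigid 3D framework in which every pair-distance
    fluctuation identifies its own spring constant.  With the default
    geometry all spring pairs are shorter than 1.2 nm and all non-spring
    pairs longer, so the hENM candidate set matches the true spring set.
    Spring constants are drawn uniformly from ``k_range`` (kJ/mol/nm^2).
    Returns ``(positions, SpringNetwork)``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_beads)
    pos = np.column_stack([radius * np.cos(twist * t),
                           radius * np.sin(twist * t), rise * t])
    pairs = np.array([(i, j) for i in range(n_beads)
                      for j in (i + 1, i + 2, i + 3) if j < n_beads])
    k = rng.uniform(*k_range, size=len(pairs))
    r0 = np.linalg.norm(pos[pairs[:, 1]] - pos[pairs[:, 0]], axis=1)
    return pos, SpringNetwork(pairs, k, r0)


# --- reduced-resolution bilayer patches ---------------------------------------

def gen_bilayer_patch(
    n_pl: int = 128,
    tg_percent: float = 2.0,
    mode: str = "dissolved",
    box=(15.0, 15.0, 10.0),
    seed: int = 0,
    cluster_cutoff: float = 2.0,
) -> GroupedFrame:
    """Flat two-leaflet patch at reduced (grouped) resolution.

    PL molecules occupy two leaflets on a jittered lattice, each as its
    11-group stack; TG molecules (13 groups each) are either scattered so
    that no two fall within ``cluster_cutoff`` of each other (``dissolved``)
    or packed as a disc-shaped blob at the midplane (``lens``).  The number
    of TG molecules is round(tg_percent/100 * (n_TG + n_PL)) by mole
    fraction, i.e. n_TG = round(f/(1-f) * n_pl).
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    schemes = build_default_schemes()
    f = tg_percent / 100.0
    n_tg = int(round(f / (1.0 - f) * n_pl)) if f > 0 else 0

    mol_id, mol_kind, glabel, gkind, gpos, gnat, gmass = [], [], [], [], [], [], []
    next_id = 0

    def add_molecule(kind, centers):
        nonlocal next_id
        scheme = schemes[kind]
        for (label, gk, members), c in zip(scheme.groups, centers):
            mol_id.append(next_id)
            mol_kind.append(kind)
            glabel.append(label)
            gkind.append(gk)
            gpos.append(c)
            nat = len(members) if members is not None else 1
            gnat.append(nat)
            gmass.append(nat * 13.0)
        next_id += 1

    # PL leaflets: half up, half down, on a jittered square lattice
    per_leaf = n_pl // 2
    side = int(np.ceil(np.sqrt(per_leaf)))
    spacing = box[0] / side
    z_mid = box[2] / 2
    for leaflet, zsign in (("upper", 1), ("lower", -1)):
        count = per_leaf if leaflet == "upper" else n_pl - per_leaf
        for m in range(count):
            ix, iy = divmod(m, side)
            xy = (np.array([ix, iy]) + 0.5) * spacing + rng.normal(scale=0.08, size=2)
            # 11 groups stacked from head (far from midplane) toward midplane
            depth = np.linspace(2.2, 0.2, 11)
            centers = [np.array([xy[0] % box[0], xy[1] % box[1], z_mid + zsign * d])
                       for d in depth]
            add_molecule("POPC", centers)

    # TG placement
    if n_tg:
        if mode == "dissolved":
            # grid with spacing > cutoff so all TG are singleton clusters
            spacing_tg = cluster_cutoff * 1.5
            nx = int(box[0] // spacing_tg)
            ny = int(box[1] // spacing_tg)
            if nx * ny < n_tg:
                raise ValueError(
                    f"cannot place {n_tg} dissolved TG with pairwise separation "
                    f"> {cluster_cutoff} nm in this box; use mode='lens'")
            cells = [(i, j) for i in range(nx) for j in range(ny)]
            rng.shuffle(cells)
            anchors = [np.array([(i + 0.5) * spacing_tg, (j + 0.5) * spacing_tg, z_mid])
                       for i, j in cells[:n_tg]]
        elif mode == "lens":
            disc_r = max(0.4 * np.sqrt(n_tg) * 0.45, 0.8)
            ang = rng.random(n_tg) * 2 * np.pi
            r = disc_r * np.sqrt(rng.random(n_tg))
            anchors = [np.array([box[0] / 2 + rr * np.cos(a),
                                 box[1] / 2 + rr * np.sin(a),
                                 z_mid + rng.normal(scale=0.15)])
                       for rr, a in zip(r, ang)]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for anchor in anchors:
            offsets = rng.normal(scale=0.12, size=(13, 3))
            add_molecule("TG", [anchor + o for o in offsets])

    return GroupedFrame(
        np.array(mol_id), np.array(mol_kind, dtype=object),
        np.array(glabel, dtype=object), np.array(gkind, dtype=object),
        np.array(gpos), np.array(gnat, dtype=int), box, np.array(gmass),
    )
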