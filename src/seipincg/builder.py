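"""Construction of the CG seipin/lipid systems.

Covers the whole build path: 4-residues-per-bead protein mapping, elastic
networks (uniform ENM and hENM via fluctuation matching), the 24 proteinized
PL molecules inside the HH ring, four-site CG lipids, spherical bilayers at a
requested TG mole percent, protein embedding with clash removal, oligomer
truncation variants, and the attraction-scaling interaction table.

Spring constants are quoted in kcal/mol/A^2 (the field's convention for
elastic networks) and converted to internal kJ/mol/nm^2; distances are nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .henm import SpringNetwork, build_henm as _henm_core
from .topology import CGSystem, CGTopology, build_interaction_table  # noqa: F401
from .units import KB, spring_kcal_to_internal

__all__ = [
    "SphericalBilayerSpec",
    "map_protein_cg",
    "build_enm",
    "build_henm",
    "add_proteinized_pls",
    "make_lipids",
    "build_spherical_bilayer",
    "build_flat_patch",
    "embed_protein",
    "truncate_oligomer",
    "build_default_seipin_model",
    "build_interaction_table",
    "DEFAULT_LIPID_BOND_K",
    "DEFAULT_LIPID_BOND_R0",
]

#: lipid backbone bond constant, kJ/mol/nm^2 (energy k (r-r0)^2)
DEFAULT_LIPID_BOND_K = 500.0
#: lipid bond rest length, nm
DEFAULT_LIPID_BOND_R0 = 0.75
#: PL angle constant: 0.5 kB T at 310 K, kJ/mol/rad^2, theta0 = 180 deg
DEFAULT_PL_ANGLE_K = 0.5 * KB * 310.0


# --- protein mapping ----------------------------------------------------------

def map_protein_cg(residue_positions, residue_masses=None, residues_per_bead: int = 4,
                   bond_sc: float = 2.0):
    """Map per-residue coordinates to CG beads, 4 residues per bead.

    ``residue_positions`` is (n_subunits, n_residues, 3) nm — every subunit
    must provide the same complete residue range (e.g. Arg23-Arg265, 243
    residues -> 61 beads: 60 full blocks of 4 plus one final block of 3).
    Returns ``(positions, subunit_id, bonds, bond_k, bond_r0)`` where
    consecutive beads within a subunit are bonded with constant ``bond_sc``
    (kcal/mol/A^2) at their build-time distance.
    """
    res = np.asarray(residue_positions, dtype=float)
    if res.ndim == 2:
        res = res[None]
    if res.ndim != 3:
        raise ValueError("residue_positions must be (n_subunits, n_residues, 3)")
    n_sub, n_res, _ = res.shape
    if not np.all(np.isfinite(res)):
        bad = np.argwhere(~np.isfinite(res))[0]
        raise ValueError(f"subunit {bad[0]} is missing residue {bad[1]} (non-finite)")
    if residue_masses is None:
        residue_masses = np.ones(n_res)
    w = np.asarray(residue_masses, dtype=float)

    n_beads = int(np.ceil(n_res / residues_per_bead))
    positions, subunit_id, bonds, bond_k, bond_r0 = [], [], [], [], []
    k_int = spring_kcal_to_internal(bond_sc)
    for s in range(n_sub):
        first = len(positions)
        for b in range(n_beads):
            sl = slice(b * residues_per_bead, (b + 1) * residues_per_bead)
            positions.append(np.average(res[s, sl], axis=0, weights=w[sl]))
            subunit_id.append(s)
        for b in range(n_beads - 1):
            i, j = first + b, first + b + 1
            bonds.append((i, j))
            bond_k.append(k_int)
            bond_r0.append(np.linalg.norm(positions[j] - positions[i]))
    return (np.array(positions), np.array(subunit_id, dtype=int),
            np.array(bonds, dtype=int).reshape(-1, 2),
            np.array(bond_k), np.array(bond_r0))


# --- elastic networks ---------------------------------------------------------

def build_enm(positions, sc: float = 0.2, cutoff: float = 1.5) -> SpringNetwork:
    """Uniform elastic network: one spring per bead pair closer than ``cutoff``.

    ``sc`` is the spring constant in kcal/mol/A^2 (defaults 0.2; the stiff
    variant uses 2.0), ``cutoff`` in nm (default 1.5 nm = 15 A).  Each
    spring's rest length is the build-time distance.
    """
    if sc <= 0 or cutoff <= 0:
        raise ValueError("sc and cutoff must be positive")
    pos = np.asarray(positions, dtype=float)
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    r0 = np.linalg.norm(pos[pairs[:, 1]] - pos[pairs[:, 0]], axis=1) if len(pairs) \
        else np.zeros(0)
    k = np.full(len(pairs), spring_kcal_to_internal(sc))
    return SpringNetwork(pairs, k, r0)


def build_henm(ensemble, cutoff: float = 1.2, backfill_sc: float = 0.1,
               backfill_cutoff: float = 1.1, temperature: float = 310.0,
               **kwargs) -> SpringNetwork:
    """Heterogeneous ENM by fluctuation matching against an aligned ensemble.

    Thin wrapper over the core matcher with the spring-constant arguments in
    kcal/mol/A^2: candidate pairs within ``cutoff`` (nm) are iterated until
    the model's pair-distance fluctuations match the ensemble's, and close
    pairs (< ``backfill_cutoff``) left without a spring receive the constant
    ``backfill_sc``.
    """
    return _henm_core(
        ensemble, cutoff=cutoff, temperature=temperature,
        backfill_sc=spring_kcal_to_internal(backfill_sc) if backfill_sc else None,
        backfill_cutoff=backfill_cutoff, **kwargs)


# --- lipids -------------------------------------------------------------------

_PL_TYPES = ("PL_head", "PL_interfacial", "PL_tail", "PL_tail")
_TG_TYPES = ("TG_glycerol", "TG_tail", "TG_tail", "TG_tail")


def make_lipids(kinds, bond_k: float = DEFAULT_LIPID_BOND_K,
                bond_r0: float = DEFAULT_LIPID_BOND_R0,
                pl_angle_k: float = DEFAULT_PL_ANGLE_K) -> CGTopology:
    """Topology for a list of four-site lipids; ``kinds`` holds 'PL'/'TG'.

    PL is head-interfacial-tail-tail with two harmonic angles (0.5 kB T,
    linear); TG is glycerol + three tails with no angle terms by default.
    """
    bead_types, mol_id = [], []
    bonds, bks, br0s, angles, aks, at0s = [], [], [], [], [], []
    for m, kind in enumerate(kinds):
        base = 4 * m
        types = _PL_TYPES if kind == "PL" else _TG_TYPES
        bead_types.extend(types)
        mol_id.extend([m] * 4)
        for b in range(3):
            bonds.append((base + b, base + b + 1))
            bks.append(bond_k)
            br0s.append(bond_r0)
        if kind == "PL":
            for a in range(2):
                angles.append((base + a, base + a + 1, base + a + 2))
                aks.append(pl_angle_k)
                at0s.append(np.pi)
    return CGTopology(
        np.array(bead_types, dtype=object), np.array(mol_id, dtype=int),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_k=np.array(bks), bond_r0=np.array(br0s),
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        angle_k=np.array(aks), angle_theta0=np.array(at0s),
    )


# --- proteinized PLs ----------------------------------------------------------

def add_proteinized_pls(system: CGSystem, hh_ring_center=(0.0, 0.0, 0.0),
                        hh_ring_radius: float = 2.0, n_pl: int = 24,
                        clash_cutoff: float = 0.35, spring_sc: float = 0.1,
                        spring_cutoff: float = 1.1, seed: int = 0,
                        max_retries: int = 50) -> CGSystem:
    """Place PL molecules inside the HH ring and make them part of the protein.

    ``n_pl`` (default 24) four-site PL molecules are arranged on a sunflower
    spiral inside the ring, oriented like lumenal-leaflet lipids (head toward
    the lumen, tails toward the midplane), flagged ``proteinized_PL`` and tied
    into the protein's elastic network: every proteinized-PL bead gains
    springs (constant ``spring_sc`` kcal/mol/A^2) to protein beads within
    ``spring_cutoff`` nm, with at least one spring per molecule guaranteed by
    falling back to the nearest protein bead.  Placements clashing with
    existing beads closer than ``clash_cutoff`` are re-jittered; persistent
    clashes raise.
    """
    if n_pl == 0:
        return system
    rng = np.random.default_rng(seed)
    center = np.asarray(hh_ring_center, dtype=float)
    top = system.topology
    half = 2.25  # membrane half thickness of the idealized geometry

    lipids = make_lipids(["PL"] * n_pl)
    golden = np.pi * (3 - np.sqrt(5))
    lipid_pos = np.empty((4 * n_pl, 3))
    existing = cKDTree(system.positions)
    for m in range(n_pl):
        r = hh_ring_radius * 0.85 * np.sqrt((m + 0.5) / n_pl)
        ang = m * golden
        for attempt in range(max_retries):
            xy = center[:2] + [r * np.cos(ang), r * np.sin(ang)] \
                + rng.normal(scale=0.05, size=2)
            z_head = center[2] - half
            col = np.array([[xy[0], xy[1], z_head + i * DEFAULT_LIPID_BOND_R0]
                            for i in range(4)])
            if existing.query(col)[0].min() >= clash_cutoff:
                break
            ang += 0.3
        else:
            raise RuntimeError(
                f"could not place proteinized PL {m} without clashes")
        lipid_pos[4 * m:4 * m + 4] = col

    lipids.set_flag("proteinized_PL", np.ones(lipids.n_beads, dtype=bool))
    merged = CGTopology.merge(top, lipids)
    positions = np.vstack([system.positions, lipid_pos])

    # tie into the elastic network
    prot_mask = top.bead_types == "PROT"
    prot_idx = np.nonzero(prot_mask)[0]
    prot_tree = cKDTree(system.positions[prot_idx])
    k_int = spring_kcal_to_internal(spring_sc)
    new_pairs, new_k, new_r0 = [], [], []
    for m in range(n_pl):
        got = False
        for b in range(4):
            gi = top.n_beads + 4 * m + b
            for local in prot_tree.query_ball_point(positions[gi], spring_cutoff):
                j = int(prot_idx[local])
                new_pairs.append((j, gi))
                new_k.append(k_int)
                new_r0.append(np.linalg.norm(positions[gi] - positions[j]))
                got = True
        if not got:
            gi = top.n_beads + 4 * m
            _, local = prot_tree.query(positions[gi])
            j = int(prot_idx[local])
            new_pairs.append((j, gi))
            new_k.append(k_int)
            new_r0.append(np.linalg.norm(positions[gi] - positions[j]))
    merged.springs = np.vstack([merged.springs, np.array(new_pairs, dtype=int)])
    merged.spring_k = np.concatenate([merged.spring_k, new_k])
    merged.spring_r0 = np.concatenate([merged.spring_r0, new_r0])
    return CGSystem(merged, positions, system.box)


# --- bilayers -----------------------------------------------------------------

@dataclass
class SphericalBilayerSpec:
    """Spherical-bilayer build parameters (diameter 40 or 60 nm in the study)."""

    diameter: float = 40.0  # nm, outer head-shell diameter
    tg_percent: float = 2.0  # mol% TG of all lipids
    area_per_lipid: float = 0.7  # nm^2
    leaflet_gap: float = 0.75  # nm, spacing between the two leaflets' tail ends

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not 0 <= self.tg_percent < 100:
            raise ValueError("TG percent must be in [0, 100)")


def _fibonacci_sphere(n, rng):
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i + rng.random() * 2 * np.pi
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def build_spherical_bilayer(spec: SphericalBilayerSpec, seed: int = 0,
                            box_margin: float = 6.0) -> CGSystem:
    """Two concentric spherical leaflets of 4-site PLs plus dispersed TG.

    Outer-leaflet heads sit on the sphere of the requested diameter with
    tails pointing inward; inner-leaflet heads face the vesicle interior with
    tails pointing outward, meeting at the midplane shell.  Leaflet lipid
    counts are proportional to leaflet head-shell areas at the requested area
    per lipid.  TG molecules are placed uniformly at random in the tail
    (midplane) shell to the requested mole percent, n_TG = round(f/(1-f) n_PL).
    """
    rng = np.random.default_rng(seed)
    b = DEFAULT_LIPID_BOND_R0
    lipid_len = 3 * b
    r_out = spec.diameter / 2
    r_in = r_out - (2 * lipid_len + spec.leaflet_gap)  # inner head shell
    r_mid = (r_out + r_in) / 2
    if r_in - lipid_len <= 0:
        raise ValueError("vesicle too small for the lipid length")
    n_out = int(round(4 * np.pi * r_out ** 2 / spec.area_per_lipid))
    n_in = int(round(4 * np.pi * r_in ** 2 / spec.area_per_lipid))
    n_pl = n_out + n_in
    f = spec.tg_percent / 100
    n_tg = int(round(f / (1 - f) * n_pl)) if f > 0 else 0

    kinds = ["PL"] * n_pl + ["TG"] * n_tg
    topo = make_lipids(kinds)
    pos = np.empty((topo.n_beads, 3))
    k = 0
    for n_leaf, r_head, sign in ((n_out, r_out, -1), (n_in, r_in, +1)):
        normals = _fibonacci_sphere(n_leaf, rng)
        for nrm in normals:
            for i in range(4):
                pos[k] = nrm * (r_head + sign * i * b)
                k += 1
    for _ in range(n_tg):
        nrm = rng.standard_normal(3)
        nrm /= np.linalg.norm(nrm)
        anchor = nrm * (r_mid + rng.uniform(-0.4, 0.4))
        # chain tangential to the midplane shell
        tang = np.cross(nrm, rng.standard_normal(3))
        tang /= np.linalg.norm(tang)
        base = anchor - 0.825 * tang
        pos[k:k + 4] = [base + 0.55 * i * tang for i in range(4)]
        pos[k:k + 4] += rng.normal(scale=0.03, size=(4, 3))
        k += 4

    box = np.full(3, spec.diameter + box_margin)
    return CGSystem(topo, pos + box / 2, box)


def build_flat_patch(lx: float, ly: float, lz: float, tg_percent: float = 2.0,
                     area_per_lipid: float = 0.7, seed: int = 0,
                     tg_mode: str = "dissolved") -> CGSystem:
    """Flat two-leaflet CG patch with dispersed TG, for desk-scale simulation.

    The bilayer midplane sits at z = lz/2; leaflet lipid counts come from
    the patch area at ``area_per_lipid``; TG molecules are scattered at the
    midplane ('dissolved') or packed centrally ('lens').
    """
    rng = np.random.default_rng(seed)
    b = DEFAULT_LIPID_BOND_R0
    per_leaf = int(round(lx * ly / area_per_lipid))
    n_pl = 2 * per_leaf
    f = tg_percent / 100
    n_tg = int(round(f / (1 - f) * n_pl)) if f > 0 else 0

    topo = make_lipids(["PL"] * n_pl + ["TG"] * n_tg)
    pos = np.empty((topo.n_beads, 3))
    z_mid = lz / 2
    side_x = int(np.ceil(np.sqrt(per_leaf * lx / ly)))
    side_y = int(np.ceil(per_leaf / side_x))
    k = 0
    for zsign in (+1, -1):
        placed = 0
        for ix in range(side_x):
            for iy in range(side_y):
                if placed >= per_leaf:
                    break
                xy = np.array([(ix + 0.5) * lx / side_x, (iy + 0.5) * ly / side_y])
                xy = (xy + rng.normal(scale=0.05, size=2)) % [lx, ly]
                # head outermost; terminal tail bead 0.6 b off the midplane
                # so the two leaflets' tails do not overlap
                z_head = z_mid + zsign * (3.6 * b)
                for i in range(4):
                    pos[k] = [xy[0], xy[1], z_head - zsign * i * b]
                    k += 1
                placed += 1
    if tg_mode == "dissolved":
        # spread TG on a shuffled grid so molecules start well separated
        ng = max(int(np.ceil(np.sqrt(n_tg))), 1)
        cells = [(i, j) for i in range(ng) for j in range(ng)]
        rng.shuffle(cells)
        anchors = np.array([[(i + 0.5) * lx / ng, (j + 0.5) * ly / ng, z_mid]
                            for i, j in cells[:n_tg]])
    elif tg_mode == "lens":
        r = 0.45 * np.sqrt(n_tg) * np.sqrt(rng.random(n_tg))
        a = rng.random(n_tg) * 2 * np.pi
        anchors = np.column_stack([lx / 2 + r * np.cos(a), ly / 2 + r * np.sin(a),
                                   np.full(n_tg, z_mid)])
    else:
        raise ValueError(f"unknown tg_mode {tg_mode!r}")
    for anchor in anchors:
        pos[k:k + 4] = _tg_chain(anchor, rng)
        k += 4
    return CGSystem(topo, pos, np.array([lx, ly, lz]))


def _tg_chain(anchor, rng, spacing: float = 0.55):
    """Compact 4-bead chain along a random in-plane direction, no overlaps."""
    ang = rng.random() * 2 * np.pi
    d = np.array([np.cos(ang), np.sin(ang), 0.0]) * spacing
    base = anchor - 1.5 * d
    return np.array([base + i * d for i in range(4)]) \
        + rng.normal(scale=0.03, size=(4, 3))


# --- combining protein and bilayer --------------------------------------------

def embed_protein(bilayer: CGSystem, protein: CGSystem,
                  clash_cutoff: float = 0.5, pole: str = "top") -> CGSystem:
    """Insert the protein into a bilayer, removing clashing lipids whole.

    The protein is built around the membrane midplane z=0 (cytosol +z) and is
    translated so its midplane coincides with the bilayer midplane — the top
    pole midplane shell for a vesicle (detected from the topology), or the
    flat patch midplane.  Lipid molecules with any bead within
    ``clash_cutoff`` nm of any protein bead are removed whole.
    """
    btop = bilayer.topology
    is_vesicle = _looks_spherical(bilayer)
    prot_extent = np.abs(protein.positions[:, :2]).max()
    if is_vesicle:
        center = bilayer.box / 2
        radii = np.linalg.norm(bilayer.positions - center, axis=1)
        r_mid = (radii.max() + radii.min()) / 2
        if prot_extent >= r_mid:
            raise ValueError("protein larger than the vesicle midplane radius")
        shift = center + np.array([0.0, 0.0, r_mid])
    else:
        if prot_extent >= min(bilayer.box[:2]) / 2:
            raise ValueError("protein larger than the patch")
        shift = np.array([bilayer.box[0] / 2, bilayer.box[1] / 2, bilayer.box[2] / 2])
    prot_pos = protein.positions + shift

    tree = cKDTree(prot_pos)
    d, _ = tree.query(bilayer.positions)
    clash_mol = np.unique(btop.molecule_id[d < clash_cutoff])
    keep = ~np.isin(btop.molecule_id, clash_mol)
    lip_top = btop.select(keep)
    lip_pos = bilayer.positions[keep]

    merged = CGTopology.merge(protein.topology, lip_top)
    return CGSystem(merged, np.vstack([prot_pos, lip_pos]), bilayer.box)


def _looks_spherical(system: CGSystem) -> bool:
    center = system.box / 2
    r = np.linalg.norm(system.positions - center, axis=1)
    return r.std() / max(r.mean(), 1e-9) < 0.35 and r.mean() > 5.0


def truncate_oligomer(system: CGSystem, mode: str, n: int = 6,
                      start_subunit: int = 0) -> CGSystem:
    """Remove parts of the oligomer: contiguous subunits or all TM segments.

    ``mode='remove_n_contiguous'`` removes ``n`` ring-adjacent subunits
    (default 6, leaving 5 of 11); ``mode='lumenal_only'`` removes every bead
    flagged as TM segment.  Bonded terms and springs incident to removed
    beads are deleted; non-protein beads are untouched.
    """
    top = system.topology
    n_sub = int(top.subunit_id.max()) + 1
    if mode == "remove_n_contiguous":
        if n == 0:
            return system
        if not 1 <= n < n_sub:
            raise ValueError(f"cannot remove {n} of {n_sub} subunits")
        removed = {(start_subunit + i) % n_sub for i in range(n)}
        keep = ~np.isin(top.subunit_id, list(removed)) | (top.subunit_id < 0)
    elif mode == "lumenal_only":
        keep = ~top.flag("tm_segment")
    else:
        raise ValueError(f"unknown truncation mode {mode!r}")
    return CGSystem(top.select(keep), system.positions[keep], system.box)


# --- default protein model ----------------------------------------------------

def build_default_seipin_model(seed: int = 0, sc: float = 0.2,
                               enm_cutoff: float = 1.5, n_subunits: int = 11,
                               n_proteinized_pl: int = 24,
                               geometry=None, box=(30.0, 30.0, 30.0)) -> CGSystem:
    """Default CG seipin model: idealized cage + uniform ENM + proteinized PLs.

    Geometry comes from the idealized generator unless supplied; the ENM uses
    ``sc`` kcal/mol/A^2 within ``enm_cutoff`` nm, and 24 PL molecules are
    placed inside the HH ring and tied into the network.
    """
    from .synth import gen_idealized_seipin

    geo = geometry if geometry is not None else gen_idealized_seipin(
        n_subunits=n_subunits, seed=seed)
    net = build_enm(geo.positions, sc=sc, cutoff=enm_cutoff)
    topo = CGTopology(
        np.array(["PROT"] * geo.n_beads, dtype=object),
        np.zeros(geo.n_beads, dtype=int),
        geo.subunit_id,
        dict(geo.flags),
        springs=net.pairs, spring_k=net.k, spring_r0=net.r0,
    )
    system = CGSystem(topo, geo.positions, np.asarray(box, dtype=float))
    return add_proteinized_pls(system, hh_ring_center=(0, 0, 0),
                               hh_ring_radius=geo.hh_ring_radius,
                               n_pl=n_proteinized_pl, seed=seed)
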