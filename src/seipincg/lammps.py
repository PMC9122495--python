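"""Export of CG systems to LAMMPS input formats and dump reading.

The production-scale CG simulations run in LAMMPS with tabulated pair
potentials; this module writes a ``real``-units data file (atoms with mass
200 g/mol and zero charge, harmonic bonds/springs and angles), one tabulated
pair-potential section per interaction-class pair, and an input-script
skeleton encoding the 50 fs time step, the 310 K / 100 ps Langevin
thermostat and the 1.5 nm nonbonded cutoff.  ``real`` units: A, fs,
kcal/mol.
"""

from __future__ import annotations

import os

import numpy as np

from .potentials import pair_energy_force
from .simulator import ForceField, SimulationParams
from .topology import BEAD_MASS, CGSystem

__all__ = ["export_engine_inputs", "read_engine_data", "read_engine_dump"]

_KJ_TO_KCAL = 1.0 / 4.184
_NM_TO_A = 10.0


def _dedupe(values, decimals=4):
    """Map rows of (k, r0)-like tuples to 1-based type ids."""
    keys = [tuple(np.round(v, decimals)) for v in values]
    uniq = sorted(set(keys))
    index = {u: t + 1 for t, u in enumerate(uniq)}
    return np.array([index[k] for k in keys], dtype=int), uniq


def export_engine_inputs(system: CGSystem, ff: ForceField,
                         params: SimulationParams, out_dir: str,
                         table_points: int = 1200, table_r_lo: float = 0.5):
    """Write ``system.data``, ``tables.pair`` and ``in.cg`` under ``out_dir``.

    Atom types are the force field's interaction classes; every bond and
    elastic spring becomes a harmonic bond type (k, r0 deduplicated), and the
    pair table holds one section per class pair with the scaled potential
    sampled on ``table_points`` uniform points (A, kcal/mol, kcal/mol/A).
    Returns the three file paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    top = system.topology
    n = top.n_beads
    n_types = ff.factor_matrix.shape[0]

    bond_pairs = np.vstack([top.bonds, top.springs]) if (len(top.bonds) or len(top.springs)) \
        else np.zeros((0, 2), dtype=int)
    bond_k = np.concatenate([top.bond_k, top.spring_k])
    bond_r0 = np.concatenate([top.bond_r0, top.spring_r0])
    if len(bond_pairs):
        bond_type, bond_coeffs = _dedupe(
            np.column_stack([bond_k * _KJ_TO_KCAL / 100.0, bond_r0 * _NM_TO_A]))
    else:
        bond_type, bond_coeffs = np.zeros(0, dtype=int), []
    if len(top.angles):
        angle_type, angle_coeffs = _dedupe(
            np.column_stack([top.angle_k * _KJ_TO_KCAL,
                             np.degrees(top.angle_theta0)]))
    else:
        angle_type, angle_coeffs = np.zeros(0, dtype=int), []

    data_path = os.path.join(out_dir, "system.data")
    box_a = system.box * _NM_TO_A
    pos_a = system.positions * _NM_TO_A
    with open(data_path, "w") as fh:
        fh.write("CG system (seipincg export)\n\n")
        fh.write(f"{n} atoms\n{len(bond_pairs)} bonds\n{len(top.angles)} angles\n\n")
        fh.write(f"{n_types} atom types\n")
        fh.write(f"{max(len(bond_coeffs), 1)} bond types\n")
        fh.write(f"{max(len(angle_coeffs), 1)} angle types\n\n")
        for axis, d in enumerate("xyz"):
            fh.write(f"0.000000 {box_a[axis]:.6f} {d}lo {d}hi\n")
        fh.write("\nMasses\n\n")
        for t in range(n_types):
            fh.write(f"{t + 1} {BEAD_MASS:.1f}\n")
        if bond_coeffs:
            fh.write("\nBond Coeffs\n\n")
            for t, (k, r0) in enumerate(bond_coeffs):
                fh.write(f"{t + 1} {k:.6f} {r0:.4f}\n")
        if angle_coeffs:
            fh.write("\nAngle Coeffs\n\n")
            for t, (k, th0) in enumerate(angle_coeffs):
                fh.write(f"{t + 1} {k:.6f} {th0:.4f}\n")
        fh.write("\nAtoms # full\n\n")
        for i in range(n):
            fh.write(f"{i + 1} {top.molecule_id[i] + 1} {ff.class_id[i] + 1} "
                     f"0.0 {pos_a[i, 0]:.4f} {pos_a[i, 1]:.4f} {pos_a[i, 2]:.4f}\n")
        if len(bond_pairs):
            fh.write("\nBonds\n\n")
            for bi, ((i, j), t) in enumerate(zip(bond_pairs, bond_type)):
                fh.write(f"{bi + 1} {t} {i + 1} {j + 1}\n")
        if len(top.angles):
            fh.write("\nAngles\n\n")
            for ai, ((i, j, k), t) in enumerate(zip(top.angles, angle_type)):
                fh.write(f"{ai + 1} {t} {i + 1} {j + 1} {k + 1}\n")

    table_path = os.path.join(out_dir, "tables.pair")
    pp = ff.pair_params
    r_nm = np.linspace(table_r_lo / _NM_TO_A, pp.cutoff, table_points)
    with open(table_path, "w") as fh:
        fh.write("# tabulated CG pair potentials (real units)\n")
        for a in range(n_types):
            for b in range(a, n_types):
                e, f = pair_energy_force(r_nm, ff.factor_matrix[a, b], pp)
                fh.write(f"\nPAIR_{a + 1}_{b + 1}\n")
                fh.write(f"N {table_points}\n\n")
                for k in range(table_points):
                    fh.write(f"{k + 1} {r_nm[k] * _NM_TO_A:.6f} "
                             f"{e[k] * _KJ_TO_KCAL:.8f} "
                             f"{f[k] * _KJ_TO_KCAL / _NM_TO_A:.8f}\n")

    in_path = os.path.join(out_dir, "in.cg")
    dt_fs = params.dt / 1e-3
    damp_fs = (params.damping or 100.0) / 1e-3
    with open(in_path, "w") as fh:
        fh.write("\n".join([
            "units real",
            "atom_style full",
            "boundary p p p",
            "read_data system.data",
            f"pair_style table linear {table_points}",
            "\n".join(
                f"pair_coeff {a + 1} {b + 1} tables.pair PAIR_{a + 1}_{b + 1} "
                f"{pp.cutoff * _NM_TO_A:.1f}"
                for a in range(n_types) for b in range(a, n_types)),
            "bond_style harmonic",
            "angle_style harmonic" if len(top.angles) else "# no angles",
            "special_bonds lj 0.0 0.0 1.0",
            "neighbor 3.0 bin",
            f"timestep {dt_fs:.1f}",
            f"velocity all create {params.temperature:.1f} {params.seed + 1}",
            "fix nve all nve",
            f"fix lang all langevin {params.temperature:.1f} "
            f"{params.temperature:.1f} {damp_fs:.1f} {params.seed + 1}",
            "thermo 1000",
            "dump traj all custom 1000 traj.dump id mol type x y z",
            f"run {params.n_steps}",
        ]) + "\n")
    return data_path, table_path, in_path


def read_engine_data(path: str) -> dict:
    """Minimal data-file reader: counts plus atoms/bonds/angles arrays."""
    with open(path) as fh:
        lines = fh.readlines()
    counts = {}
    for ln in lines[:20]:
        parts = ln.split()
        if len(parts) == 2 and parts[1] in ("atoms", "bonds", "angles"):
            counts[parts[1]] = int(parts[0])
    out = {"counts": counts, "atoms": [], "bonds": [], "angles": [], "masses": {}}
    section = None
    for ln in lines:
        s = ln.strip()
        base = s.split("#")[0].strip()
        if base in ("Masses", "Atoms", "Bonds", "Angles", "Bond Coeffs", "Angle Coeffs"):
            section = base
            continue
        if not base:
            continue
        parts = base.split()
        try:
            row = [float(x) for x in parts]
        except ValueError:
            section = None
            continue
        if section == "Masses":
            out["masses"][int(row[0])] = row[1]
        elif section == "Atoms":
            out["atoms"].append(row)
        elif section == "Bonds":
            out["bonds"].append([int(x) for x in row])
        elif section == "Angles":
            out["angles"].append([int(x) for x in row])
    for key in ("atoms", "bonds", "angles"):
        out[key] = np.array(out[key])
    return out


def read_engine_dump(path: str):
    """Read a LAMMPS text dump into frames with stable bead ordering.

    Expects ``ITEM: ATOMS`` columns including id, x, y, z (plus optional mol
    and type); coordinates are converted from A to nm.  Yields dicts with
    ``step``, ``box`` (nm) and ``positions`` (n_atoms, 3) sorted by atom id.
    Malformed frames raise with the byte offset of the frame header.
    """
    frames = []
    with open(path) as fh:
        while True:
            offset = fh.tell()
            header = fh.readline()
            if not header:
                break
            try:
                if not header.startswith("ITEM: TIMESTEP"):
                    raise ValueError("expected ITEM: TIMESTEP")
                step = int(fh.readline())
                if not fh.readline().startswith("ITEM: NUMBER OF ATOMS"):
                    raise ValueError("expected ITEM: NUMBER OF ATOMS")
                n = int(fh.readline())
                if not fh.readline().startswith("ITEM: BOX BOUNDS"):
                    raise ValueError("expected ITEM: BOX BOUNDS")
                bounds = [[float(x) for x in fh.readline().split()[:2]]
                          for _ in range(3)]
                atoms_line = fh.readline()
                if not atoms_line.startswith("ITEM: ATOMS"):
                    raise ValueError("expected ITEM: ATOMS")
                cols = atoms_line.split()[2:]
                idx = {c: cols.index(c) for c in ("id", "x", "y", "z")}
                rows = np.array([[float(x) for x in fh.readline().split()]
                                 for _ in range(n)])
                if rows.shape != (n, len(cols)):
                    raise ValueError("truncated atom block")
            except (ValueError, IndexError) as err:
                raise ValueError(
                    f"malformed dump frame at byte offset {offset}: {err}") from None
            order = np.argsort(rows[:, idx["id"]])
            pos = rows[np.ix_(order, [idx["x"], idx["y"], idx["z"]])] / _NM_TO_A
            box = np.array([hi - lo for lo, hi in bounds]) / _NM_TO_A
            frames.append({"step": step, "box": box, "positions": pos})
    return frames
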