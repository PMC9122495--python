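"""Reduced-resolution mapping of atomistic molecules onto molecular groups.

Lipids and protein residues are coarsened to a small number of chemically
meaningful groups before any interaction analysis: each POPC molecule becomes
11 groups (choline head, phosphate, glycerol moiety, and four tail groups per
acyl chain), each triolein (TG) molecule becomes 13 groups (glycerol moiety
plus four tail groups per each of three acyl chains), and each protein
residue becomes one backbone and one side-chain group.  Group positions are
mass-weighted centers of their member atoms.

Atom-name membership follows one shipped naming dialect (CHARMM-style heavy
atoms; hydrogen masses are assumed folded into their parent heavy atoms, or
explicit per-atom masses may be supplied).  Unknown atom names fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GroupingScheme",
    "GroupedFrame",
    "MappingError",
    "UnknownAtomError",
    "MissingSchemeError",
    "build_default_schemes",
    "map_frame",
    "map_trajectory",
]

# Standard atomic masses, g/mol; element inferred from the leading letter of
# the atom name.  Used when explicit masses are not given.
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
}

#: sentinel member list meaning "all atoms not claimed by another group"
REST = None


class MappingError(ValueError):
    pass


class UnknownAtomError(MappingError):
    def __init__(self, molecule_id, molecule_kind, atom_name):
        self.molecule_id = molecule_id
        self.atom_name = atom_name
        super().__init__(
            f"atom name {atom_name!r} in molecule {molecule_id} "
            f"({molecule_kind}) is not a member of any group of its scheme"
        )


class MissingSchemeError(MappingError):
    def __init__(self, molecule_kind):
        super().__init__(f"no grouping scheme registered for molecule kind {molecule_kind!r}")


@dataclass(frozen=True)
class GroupingScheme:
    """Partition of one molecule kind's atoms into named groups."""

    molecule_kind: str  # 'POPC' | 'TG' | 'residue'
    groups: tuple  # of (label, kind, member_atom_names tuple | REST)

    def __post_init__(self):
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise MappingError("duplicate group labels in scheme")
        n_rest = sum(1 for g in self.groups if g[2] is REST)
        if n_rest > 1:
            raise MappingError("at most one catch-all group allowed per scheme")
        named = [n for g in self.groups if g[2] is not REST for n in g[2]]
        if len(set(named)) != len(named):
            raise MappingError("atom assigned to more than one group")
        kinds = [g[1] for g in self.groups]
        if self.molecule_kind == "POPC" and len(self.groups) != 11:
            raise MappingError("POPC scheme must have exactly 11 groups")
        if self.molecule_kind == "TG":
            if len(self.groups) != 13 or kinds.count("tail") != 12 or kinds.count("glycerol") != 1:
                raise MappingError("TG scheme must have 12 tail groups and 1 glycerol group")
        if self.molecule_kind == "residue" and len(self.groups) != 2:
            raise MappingError("residue scheme must have exactly 2 groups")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def atom_to_group(self) -> dict:
        """name -> group index; the catch-all group is absent from the map."""
        out = {}
        for gi, (_, _, members) in enumerate(self.groups):
            if members is REST:
                continue
            for name in members:
                out[name] = gi
        return out

    def rest_group_index(self):
        for gi, (_, _, members) in enumerate(self.groups):
            if members is REST:
                return gi
        return None


@dataclass
class GroupedFrame:
    """One reduced-resolution snapshot.

    Arrays are parallel over group entries; ``box`` is the orthorhombic
    periodic box edge lengths in nm.
    """

    molecule_id: np.ndarray  # (N,) int
    molecule_kind: np.ndarray  # (N,) str
    group_label: np.ndarray  # (N,) str
    group_kind: np.ndarray  # (N,) str
    positions: np.ndarray  # (N, 3) float, nm
    n_member_atoms: np.ndarray  # (N,) int
    box: np.ndarray  # (3,) float, nm
    group_mass: np.ndarray = field(default=None)  # (N,) float, optional

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise MappingError("non-finite group position")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise MappingError("positions must be (N, 3)")
        n = len(self.positions)
        for name in ("molecule_id", "molecule_kind", "group_label", "group_kind", "n_member_atoms"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise MappingError(f"{name} length mismatch")
            setattr(self, name, arr)
        if np.any(self.n_member_atoms < 1):
            raise MappingError("every group needs at least one member atom")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, mask: np.ndarray) -> "GroupedFrame":
        gm = self.group_mass[mask] if self.group_mass is not None else None
        return GroupedFrame(
            self.molecule_id[mask], self.molecule_kind[mask], self.group_label[mask],
            self.group_kind[mask], self.positions[mask], self.n_member_atoms[mask],
            self.box, gm,
        )

    def molecule_count(self, kind: str) -> int:
        return len(np.unique(self.molecule_id[self.molecule_kind == kind]))


def _blocks(names: Sequence[str], n_blocks: int = 4):
    """Split a chain's carbon names into ``n_blocks`` contiguous tail blocks,
    as evenly as possible, extra atoms going to the terminal-most blocks."""
    n = len(names)
    base, extra = divmod(n, n_blocks)
    sizes = [base + (1 if i >= n_blocks - extra else 0) for i in range(n_blocks)]
    out, start = [], 0
    for s in sizes:
        out.append(tuple(names[start:start + s]))
        start += s
    return out


def build_default_schemes() -> dict:
    """Default grouping schemes keyed by molecule kind.

    POPC: choline + phosphate + glycerol moiety (incl. ester/carbonyl atoms)
    + 4 tail groups per acyl chain = 11 groups.  TG (triolein): glycerol
    moiety (incl. the three ester groups) + 4 tail groups per chain = 13
    groups.  Protein residue: backbone + side chain.
    """
    # POPC, CHARMM-style heavy-atom names.  sn-1 palmitoyl C32..C316 (15
    # chain carbons), sn-2 oleoyl C22..C218 (17 chain carbons).
    sn1 = [f"C3{i}" for i in range(2, 17)]
    sn2 = [f"C2{i}" for i in range(2, 19)]
    popc_groups = [
        ("choline", "head", ("N", "C11", "C12", "C13", "C14", "C15")),
        ("phosphate", "phosphate", ("P", "O11", "O12", "O13", "O14")),
        ("glycerol", "glycerol",
         ("C1", "C2", "C3", "O21", "C21", "O22", "O31", "C31", "O32")),
    ]
    for ci, chain in (("sn1", sn1), ("sn2", sn2)):
        for bi, block in enumerate(_blocks(chain), start=1):
            popc_groups.append((f"{ci}_t{bi}", "tail", block))
    popc = GroupingScheme("POPC", tuple(popc_groups))

    # Triolein: three oleoyl chains a/b/c with 17 chain carbons each.
    tg_groups = [(
        "glycerol", "glycerol",
        ("C1", "C2", "C3",
         "O11", "C11", "O12", "O21", "C21", "O22", "O31", "C31", "O32"),
    )]
    for ci, prefix in (("a", "C1"), ("b", "C2"), ("c", "C3")):
        chain = [f"{prefix}{i}" for i in range(2, 19)]
        for bi, block in enumerate(_blocks(chain), start=1):
            tg_groups.append((f"{ci}_t{bi}", "tail", block))
    tg = GroupingScheme("TG", tuple(tg_groups))

    residue = GroupingScheme("residue", (
        ("backbone", "backbone", ("N", "CA", "C", "O", "OXT")),
        ("sidechain", "sidechain", REST),
    ))
    return {"POPC": popc, "TG": tg, "residue": residue}


def _atom_masses(names: np.ndarray, masses) -> np.ndarray:
    if masses is not None:
        m = np.asarray(masses, dtype=float)
        if len(m) != len(names):
            raise MappingError("masses length mismatch")
        return m
    out = np.empty(len(names))
    for i, name in enumerate(names):
        elem = next((c for c in str(name) if c.isalpha()), "")
        try:
            out[i] = _ELEMENT_MASSES[elem.upper()]
        except KeyError:
            raise MappingError(f"cannot infer element for atom name {name!r}; pass masses")
    return out


def map_frame(
    positions,
    atom_names,
    molecule_ids,
    molecule_kinds,
    box,
    schemes: Mapping[str, GroupingScheme] | None = None,
    masses=None,
) -> GroupedFrame:
    """Map one atomistic frame to its reduced-resolution groups.

    Parameters
    ----------
    positions : (n_atoms, 3) array, nm
    atom_names, molecule_ids, molecule_kinds : per-atom arrays
    box : (3,) orthorhombic box, nm
    schemes : kind -> GroupingScheme (defaults to :func:`build_default_schemes`)
    masses : optional per-atom masses, g/mol; inferred from element otherwise
    """
    if schemes is None:
        schemes = build_default_schemes()
    positions = np.asarray(positions, dtype=float)
    atom_names = np.asarray(atom_names)
    molecule_ids = np.asarray(molecule_ids)
    molecule_kinds = np.asarray(molecule_kinds)

    # validate molecule kinds and atom-name membership before touching masses
    assignments = []
    _, first = np.unique(molecule_ids, return_index=True)
    mol_order = molecule_ids[np.sort(first)]
    for mol in mol_order:
        sel = molecule_ids == mol
        kind = molecule_kinds[sel][0]
        if kind not in schemes:
            raise MissingSchemeError(kind)
        scheme = schemes[kind]
        a2g = scheme.atom_to_group()
        rest = scheme.rest_group_index()
        gidx = np.empty(sel.sum(), dtype=int)
        for i, name in enumerate(atom_names[sel]):
            gi = a2g.get(str(name), rest)
            if gi is None:
                raise UnknownAtomError(mol, kind, str(name))
            gidx[i] = gi
        assignments.append((mol, sel, scheme, kind, gidx))
    m = _atom_masses(atom_names, masses)

    out = {k: [] for k in
           ("molecule_id", "molecule_kind", "group_label", "group_kind",
            "positions", "n_member_atoms", "group_mass")}
    for mol, sel, scheme, kind, gidx in assignments:
        pos, mm = positions[sel], m[sel]
        for gi, (label, gkind, _) in enumerate(scheme.groups):
            members = gidx == gi
            if not members.any():
                raise MappingError(
                    f"group {label!r} of molecule {mol} ({kind}) has no atoms")
            w = mm[members]
            out["molecule_id"].append(mol)
            out["molecule_kind"].append(kind)
            out["group_label"].append(label)
            out["group_kind"].append(gkind)
            out["positions"].append(np.average(pos[members], axis=0, weights=w))
            out["n_member_atoms"].append(int(members.sum()))
            out["group_mass"].append(float(w.sum()))
    return GroupedFrame(
        np.asarray(out["molecule_id"]),
        np.asarray(out["molecule_kind"], dtype=object),
        np.asarray(out["group_label"], dtype=object),
        np.asarray(out["group_kind"], dtype=object),
        np.asarray(out["positions"]),
        np.asarray(out["n_member_atoms"], dtype=int),
        box,
        np.asarray(out["group_mass"]),
    )


def map_trajectory(
    frames,
    atom_names=None,
    molecule_ids=None,
    molecule_kinds=None,
    schemes=None,
    masses=None,
) -> list:
    """Map a whole trajectory, one :class:`GroupedFrame` per input frame.

    ``frames`` may be an ``MDAnalysis.Universe`` (atom names, residue ids and
    masses are taken from its topology; resnames POPC map to the POPC scheme,
    TRIO/TRIL/TG to the TG scheme, everything else to the residue scheme), or
    an iterable of ``(positions, box)`` tuples with the per-atom metadata
    passed explicitly.
    """
    out = []
    try:
        import MDAnalysis as mda
        is_universe = isinstance(frames, mda.Universe)
    except ImportError:  # pragma: no cover - MDAnalysis is a hard dependency
        is_universe = False
    if is_universe:
        u = frames
        names = u.atoms.names
        resnames = u.atoms.resnames
        lipid_kinds = {"POPC": "POPC", "TRIO": "TG", "TRIL": "TG", "TG": "TG"}
        kinds = np.array([lipid_kinds.get(rn, "residue") for rn in resnames], dtype=object)
        mol_ids = u.atoms.resindices
        try:
            masses_u = u.atoms.masses
        except Exception:
            masses_u = None
        for ts in u.trajectory:
            pos = ts.positions * 0.1  # A -> nm
            box = ts.dimensions[:3] * 0.1
            out.append(map_frame(pos, names, mol_ids, kinds, box, schemes, masses_u))
        return out

    n_expected = None
    for fi, (pos, box) in enumerate(frames):
        pos = np.asarray(pos, dtype=float)
        if n_expected is None:
            n_expected = len(pos)
        elif len(pos) != n_expected:
            raise MappingError(
                f"frame {fi}: atom count {len(pos)} differs from {n_expected}")
        out.append(map_frame(pos, atom_names, molecule_ids, molecule_kinds,
                             box, schemes, masses))
    return out
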