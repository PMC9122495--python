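"""CG topology containers and the attraction-scaling interaction table.

Every CG bead carries a mass of 200 g/mol and no charge.  Lipids are linear
four-site molecules (PL: head, interfacial, tail, tail; TG: glycerol plus
three tail beads).  Protein beads carry annotation flags that drive both the
geometry operations (TM truncation, neck measurement) and the nonbonded
attraction scaling: protein beads in the hydrophobic phase attract PL tails
at factor 1, interfacial protein beads attract PL interfacial beads at 1.5,
the two hydrophobic-helix beads and the four central beads of each TM
segment attract TG at 1.5, and the TM terminal tips attract the PL
interface/head at a configurable factor r (the quantity varied in the
tip-mutant computational experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BEAD_MASS",
    "BEAD_TYPES",
    "FLAGS",
    "CGTopology",
    "CGSystem",
    "InteractionTable",
    "build_interaction_table",
]

#: g/mol, identical for every CG bead
BEAD_MASS = 200.0

BEAD_TYPES = ("PL_head", "PL_interfacial", "PL_tail", "TG_glycerol", "TG_tail", "PROT")

FLAGS = (
    "hydrophobic_phase",
    "interfacial",
    "TG_attractive_HH",
    "TG_attractive_TM_core",
    "TM_terminal_tip",
    "proteinized_PL",
    "tm_segment",
    "lumenal_domain",
    "hh",
)


@dataclass
class CGTopology:
    """Beads, bonded terms and elastic springs of a CG system."""

    bead_types: np.ndarray  # (N,) str
    molecule_id: np.ndarray  # (N,) int
    subunit_id: np.ndarray = None  # (N,) int, -1 for non-protein
    flags: dict = field(default_factory=dict)  # flag -> (N,) bool
    bonds: np.ndarray = None  # (nb, 2) int
    bond_k: np.ndarray = None  # kJ/mol/nm^2, energy k (r - r0)^2
    bond_r0: np.ndarray = None  # nm
    angles: np.ndarray = None  # (na, 3) int
    angle_k: np.ndarray = None  # kJ/mol/rad^2, energy k (theta - theta0)^2
    angle_theta0: np.ndarray = None  # rad
    springs: np.ndarray = None  # (ns, 2) int — elastic-network springs
    spring_k: np.ndarray = None
    spring_r0: np.ndarray = None

    def __post_init__(self):
        self.bead_types = np.asarray(self.bead_types, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        n = len(self.bead_types)
        if self.subunit_id is None:
            self.subunit_id = np.full(n, -1, dtype=int)
        self.subunit_id = np.asarray(self.subunit_id, dtype=int)
        for name in ("bonds", "angles", "springs"):
            if getattr(self, name) is None:
                width = 3 if name == "angles" else 2
                setattr(self, name, np.zeros((0, width), dtype=int))
            else:
                setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in ("bond_k", "bond_r0", "spring_k", "spring_r0",
                     "angle_k", "angle_theta0"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(0))
            else:
                setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for flag in list(self.flags):
            self.flags[flag] = np.asarray(self.flags[flag], dtype=bool)
        unknown = set(self.bead_types) - set(BEAD_TYPES)
        if unknown:
            raise ValueError(f"unknown bead types {unknown}")
        if len(self.springs):
            key = (self.springs.min(axis=1).astype(np.int64) * n
                   + self.springs.max(axis=1))
            if len(np.unique(key)) != len(key):
                raise ValueError("duplicate elastic springs for a bead pair")
        if np.any(self.spring_k < 0) or np.any(self.bond_k < 0):
            raise ValueError("negative force constant")

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def masses(self) -> np.ndarray:
        return np.full(self.n_beads, BEAD_MASS)

    @property
    def charges(self) -> np.ndarray:
        return np.zeros(self.n_beads)

    def flag(self, name: str) -> np.ndarray:
        return self.flags.get(name, np.zeros(self.n_beads, dtype=bool))

    def set_flag(self, name: str, mask) -> None:
        if name not in FLAGS:
            raise ValueError(f"unknown flag {name!r}")
        self.flags[name] = np.asarray(mask, dtype=bool)

    def bead_flags(self, i: int) -> frozenset:
        return frozenset(f for f, m in self.flags.items() if m[i])

    def select(self, keep: np.ndarray) -> "CGTopology":
        """Induced sub-topology on the kept beads (bonded terms filtered)."""
        keep = np.asarray(keep, dtype=bool)
        newidx = np.full(self.n_beads, -1, dtype=int)
        newidx[keep] = np.arange(keep.sum())

        def filt(pairs, *cols):
            ok = keep[pairs].all(axis=1) if len(pairs) else np.zeros(0, dtype=bool)
            return (newidx[pairs[ok]],) + tuple(c[ok] for c in cols)

        bonds, bond_k, bond_r0 = filt(self.bonds, self.bond_k, self.bond_r0)
        angles, angle_k, angle_theta0 = filt(self.angles, self.angle_k, self.angle_theta0)
        springs, spring_k, spring_r0 = filt(self.springs, self.spring_k, self.spring_r0)
        return CGTopology(
            self.bead_types[keep], self.molecule_id[keep], self.subunit_id[keep],
            {f: m[keep] for f, m in self.flags.items()},
            bonds, bond_k, bond_r0, angles, angle_k, angle_theta0,
            springs, spring_k, spring_r0,
        )

    @staticmethod
    def merge(a: "CGTopology", b: "CGTopology") -> "CGTopology":
        off = a.n_beads
        mol_off = a.molecule_id.max() + 1 if a.n_beads else 0
        sub_off = max(a.subunit_id.max() + 1, 0) if a.n_beads else 0
        flags = {}
        for f in set(a.flags) | set(b.flags):
            flags[f] = np.concatenate([a.flag(f), b.flag(f)])
        b_sub = np.where(b.subunit_id >= 0, b.subunit_id + sub_off, -1)
        return CGTopology(
            np.concatenate([a.bead_types, b.bead_types]),
            np.concatenate([a.molecule_id, b.molecule_id + mol_off]),
            np.concatenate([a.subunit_id, b_sub]),
            flags,
            np.vstack([a.bonds, b.bonds + off]),
            np.concatenate([a.bond_k, b.bond_k]),
            np.concatenate([a.bond_r0, b.bond_r0]),
            np.vstack([a.angles, b.angles + off]),
            np.concatenate([a.angle_k, b.angle_k]),
            np.concatenate([a.angle_theta0, b.angle_theta0]),
            np.vstack([a.springs, b.springs + off]),
            np.concatenate([a.spring_k, b.spring_k]),
            np.concatenate([a.spring_r0, b.spring_r0]),
        )


@dataclass
class CGSystem:
    """A topology together with bead coordinates and a periodic box."""

    topology: CGTopology
    positions: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if len(self.positions) != self.topology.n_beads:
            raise ValueError("positions/topology size mismatch")


# --- attraction-scaling table -------------------------------------------------

# selectors are either a bead-type name or a flag name
_DEFAULT_RULES = [
    # lipid-lipid base attractions (factor 1 = the PL tail-tail depth)
    ("PL_tail", "PL_tail", 1.0),
    ("PL_interfacial", "PL_interfacial", 1.0),
    ("PL_tail", "TG_tail", 1.0),
    ("TG_tail", "TG_tail", 1.0),
    ("TG_glycerol", "TG_glycerol", 1.0),
    ("TG_glycerol", "PL_interfacial", 1.0),
    # protein-lipid: hydrophobic-phase beads behave like tail beads
    ("hydrophobic_phase", "PL_tail", 1.0),
    ("hydrophobic_phase", "TG_tail", 1.0),
    # membrane-interface protein beads attract the PL interface at 1.5
    ("interfacial", "PL_interfacial", 1.5),
    # HH pair and TM-core beads attract TG (both bead kinds) at 1.5
    ("TG_attractive_HH", "TG_tail", 1.5),
    ("TG_attractive_HH", "TG_glycerol", 1.5),
    ("TG_attractive_TM_core", "TG_tail", 1.5),
    ("TG_attractive_TM_core", "TG_glycerol", 1.5),
]

DEFAULT_TIP_SCALING = 1.5


@dataclass
class InteractionTable:
    """Ordered attraction-scaling rules; the last matching rule wins.

    Each rule pairs two selectors (a bead type or an annotation flag) with a
    non-negative factor that multiplies the base attraction depth and force
    linearly.  Lookup is symmetric.
    """

    rules: list  # of (selector_a, selector_b, factor)

    def __post_init__(self):
        valid = set(BEAD_TYPES) | set(FLAGS)
        for a, b, f in self.rules:
            if a not in valid or b not in valid:
                raise ValueError(f"unknown selector in rule ({a!r}, {b!r})")
            if f < 0:
                raise ValueError(f"negative scaling factor for ({a}, {b})")

    @staticmethod
    def _matches(sel: str, bead_type: str, flags: frozenset) -> bool:
        return sel == bead_type or sel in flags

    def factor(self, type_a: str, flags_a, type_b: str, flags_b) -> float:
        """Scaling factor for a bead pair described by (type, flags) each."""
        flags_a, flags_b = frozenset(flags_a), frozenset(flags_b)
        out = 0.0
        for sa, sb, f in self.rules:
            if (self._matches(sa, type_a, flags_a) and self._matches(sb, type_b, flags_b)) or \
               (self._matches(sa, type_b, flags_b) and self._matches(sb, type_a, flags_a)):
                out = f
        return out


def build_interaction_table(overrides=None, tip_scaling_r: float = DEFAULT_TIP_SCALING
                            ) -> InteractionTable:
    """Default attraction-scaling table with optional overrides.

    ``overrides`` maps (selector_a, selector_b) tuples to factors and is
    applied after every default rule.  ``tip_scaling_r`` is the TM-tip to
    PL-interface/head factor (the r varied in the tip-mutant experiments).
    """
    if tip_scaling_r < 0:
        raise ValueError("negative tip scaling factor")
    rules = list(_DEFAULT_RULES)
    rules.append(("TM_terminal_tip", "PL_interfacial", tip_scaling_r))
    rules.append(("TM_terminal_tip", "PL_head", tip_scaling_r))
    if overrides:
        for (a, b), f in overrides.items():
            rules.append((a, b, float(f)))
    return InteractionTable(rules)
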