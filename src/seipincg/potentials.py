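"""Nonbonded pair-potential family and tabulation.

The study-scale CG force field uses tabulated pair potentials whose
attraction depth and force scale linearly with a per-pair factor.  This
package ships one documented parametric family in that spirit — a
solvent-free membrane form: a Weeks-Chandler-Andersen repulsive core plus a
cos^2 attractive well that goes smoothly to zero at the cutoff,

    E(r) = E_WCA(r; sigma, eps_rep) - f * eps_att * w(r)
    w(r) = 1                                   r <  r_m = 2^(1/6) sigma
         = cos^2( pi (r - r_m) / (2 w_c) )     r_m <= r < r_c
         = 0                                   r >= r_c,  w_c = r_c - r_m

so a pair with factor f = 0 is purely repulsive and doubling f exactly
doubles the well depth and the attractive force.  Externally supplied tables
can be evaluated instead of the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairParams", "pair_energy_force", "PotentialTable", "tabulate"]


@dataclass(frozen=True)
class PairParams:
    """Parameters of the nonbonded family (internal units: nm, kJ/mol)."""

    sigma: float = 0.65  # bead diameter, nm
    eps_rep: float = 2.5  # WCA strength, kJ/mol
    eps_att: float = 4.5  # attraction depth at factor 1, kJ/mol (~1.75 kBT at 310 K)
    cutoff: float = 1.5  # nm

    @property
    def r_min(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def well_width(self) -> float:
        return self.cutoff - self.r_min


def pair_energy_force(r, factor, params: PairParams = PairParams()):
    """Energy (kJ/mol) and radial force magnitude F = -dE/dr (kJ/mol/nm).

    Vectorised over ``r``; raises for non-positive separations.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    s, er, ea, rc = params.sigma, params.eps_rep, factor * params.eps_att, params.cutoff
    rm, w = params.r_min, params.well_width
    E = np.zeros_like(r)
    F = np.zeros_like(r)

    core = r < rm
    if core.any():
        sr6 = (s / r[core]) ** 6
        E[core] = 4 * er * (sr6 ** 2 - sr6) + er - ea
        F[core] = 4 * er * (12 * sr6 ** 2 - 6 * sr6) / r[core]

    tail = (r >= rm) & (r < rc)
    if tail.any():
        x = np.pi * (r[tail] - rm) / (2 * w)
        E[tail] = -ea * np.cos(x) ** 2
        F[tail] = -ea * np.pi / (2 * w) * np.sin(2 * x)
    if scalar:
        return float(E[0]), float(F[0])
    return E, F


@dataclass
class PotentialTable:
    """Uniformly gridded (r, E, F) samples of one pair potential.

    Units follow the internal convention (nm, kJ/mol, kJ/mol/nm); the energy
    is zero at the cutoff and the force column is consistent with -dE/dr.
    """

    r: np.ndarray
    energy: np.ndarray
    force: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        dr = np.diff(self.r)
        if not np.allclose(dr, dr[0]):
            raise ValueError("table grid must be uniform")

    def evaluate(self, r):
        """Linear interpolation of energy and force at distances ``r``."""
        e = np.interp(r, self.r, self.energy, right=0.0)
        f = np.interp(r, self.r, self.force, right=0.0)
        return e, f

    def check_consistency(self, rtol: float = 1e-3) -> float:
        """Max relative deviation of F from -dE/dr by central difference."""
        dr = self.r[1] - self.r[0]
        fd = -(self.energy[2:] - self.energy[:-2]) / (2 * dr)
        ref = np.abs(self.force[1:-1])
        scale = max(ref.max(), 1e-12)
        return float(np.max(np.abs(fd - self.force[1:-1]) / scale))


def tabulate(factor: float, params: PairParams = PairParams(),
             r_lo: float = 0.3, n_points: int = 1200) -> PotentialTable:
    """Sample the closed form on a uniform grid up to the cutoff."""
    r = np.linspace(r_lo, params.cutoff, n_points)
    e, f = pair_energy_force(r, factor, params)
    return PotentialTable(r, e, f)
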