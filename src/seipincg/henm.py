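"""Harmonic-network math: Hessians, thermal covariances, fluctuation matching.

The elastic energy of a spring network is E = sum_ij k_ij (r_ij - r0_ij)^2
(no 1/2 prefactor, matching the bond-potential convention used throughout
the package).  At the equilibrium structure the Hessian contribution of one
spring is 2 k n n^T on the (i, i)/(j, j) blocks and -2 k n n^T on the
cross blocks, with n the unit bond vector.  The thermal covariance is
C = kB T H^+ with the rigid-body null space removed, which gives both
per-bead RMSFs and linearised pair-distance variances

    var(d_ij) ~= n^T (C_ii + C_jj - 2 C_ij) n.

Heterogeneous-ENM (hENM) construction inverts this map: spring constants are
iterated until the model's pair-distance fluctuations match those measured
from a reference ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import kBT

__all__ = [
    "SpringNetwork",
    "network_hessian",
    "thermal_covariance",
    "distance_variances",
    "model_rmsf",
    "build_henm",
    "HenmConvergenceError",
]

_RIGID_TOL = 1e-9


@dataclass
class SpringNetwork:
    """Pairs (i, j), spring constants k (kJ/mol/nm^2) and rest lengths r0 (nm)."""

    pairs: np.ndarray  # (n_springs, 2) int
    k: np.ndarray  # (n_springs,) kJ/mol/nm^2
    r0: np.ndarray  # (n_springs,) nm

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.k = np.asarray(self.k, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        if len(self.pairs):
            nmax = self.pairs.max() + 1
            key = self.pairs.min(axis=1) * nmax + self.pairs.max(axis=1)
            if len(np.unique(key)) != len(key):
                raise ValueError("duplicate springs for a bead pair")
        if np.any(self.k <= 0):
            raise ValueError("spring constants must be positive")

    def __len__(self):
        return len(self.pairs)


def network_hessian(positions, network: SpringNetwork) -> np.ndarray:
    """(3N, 3N) Hessian of the network energy at ``positions`` (equilibrium)."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    h = np.zeros((3 * n, 3 * n))
    for (i, j), k in zip(network.pairs, network.k):
        d = pos[j] - pos[i]
        r = np.linalg.norm(d)
        if r == 0:
            raise ValueError(f"coincident beads {i}, {j}")
        nvec = d / r
        blk = 2.0 * k * np.outer(nvec, nvec)
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] += blk
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] += blk
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= blk
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= blk
    return h


def thermal_covariance(positions, network: SpringNetwork, temperature: float):
    """kB T pseudoinverse of the Hessian, rigid/zero modes removed.

    Returns ``(cov, n_zero_modes)``; ``cov`` is (3N, 3N) in nm^2.
    """
    h = network_hessian(positions, network)
    w, v = np.linalg.eigh(h)
    scale = max(w.max(), 1.0)
    nonzero = w > _RIGID_TOL * scale
    inv = np.zeros_like(w)
    inv[nonzero] = 1.0 / w[nonzero]
    cov = kBT(temperature) * (v * inv) @ v.T
    return cov, int((~nonzero).sum())


def distance_variances(positions, cov, pairs) -> np.ndarray:
    """Linearised variances of pair distances from a positional covariance."""
    pos = np.asarray(positions, dtype=float)
    out = np.empty(len(pairs))
    for s, (i, j) in enumerate(pairs):
        d = pos[j] - pos[i]
        nvec = d / np.linalg.norm(d)
        block = (cov[3 * i:3 * i + 3, 3 * i:3 * i + 3]
                 + cov[3 * j:3 * j + 3, 3 * j:3 * j + 3]
                 - cov[3 * i:3 * i + 3, 3 * j:3 * j + 3]
                 - cov[3 * j:3 * j + 3, 3 * i:3 * i + 3])
        out[s] = nvec @ block @ nvec
    return out


def model_rmsf(positions, network: SpringNetwork, temperature: float) -> np.ndarray:
    """Analytic per-bead RMSF (nm) of the harmonic network at ``temperature``."""
    cov, _ = thermal_covariance(positions, network, temperature)
    n = len(positions)
    return np.sqrt(np.array([np.trace(cov[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                             for i in range(n)]))


class HenmConvergenceError(RuntimeError):
    def __init__(self, n_iter, residual):
        self.residual = residual
        super().__init__(
            f"hENM fluctuation matching did not converge in {n_iter} iterations; "
            f"max relative fluctuation mismatch {residual:.3g}")


def build_henm(
    ensemble,
    cutoff: float = 1.2,
    temperature: float = 310.0,
    backfill_sc: float | None = None,
    backfill_cutoff: float = 1.1,
    k_init: float = 100.0,
    k_floor: float = 1.0,
    alpha: float = 0.7,
    tol: float = 5e-3,
    max_iter: int = 500,
    rigid_sigma_floor: float = 1e-6,
) -> SpringNetwork:
    """Heterogeneous elastic network by iterative distance-fluctuation matching.

    Parameters
    ----------
    ensemble : (n_samples, n_beads, 3) nm, rigid-body aligned
    cutoff : nm — candidate springs are pairs with mean distance < cutoff
        (default 1.2 nm, i.e. 12 A)
    backfill_sc : kJ/mol/nm^2 — constant applied to close pairs (< backfill
        cutoff, default 1.1 nm) that end up without an hENM spring; omitted
        when None
    k_init, k_floor : initial and pruning spring constants, kJ/mol/nm^2;
        springs whose matched constant falls below ``k_floor`` are removed
    alpha : damping exponent of the multiplicative update
        k <- k (var_model / var_target)^alpha
    tol : convergence tolerance on the max relative fluctuation mismatch
    rigid_sigma_floor : nm — a pair whose measured distance fluctuation is
        below this is treated as rigid (degenerate input) and rejected

    Notes
    -----
    Needs at least 100 samples for usable fluctuation statistics.
    """
    ens = np.asarray(ensemble, dtype=float)
    if ens.ndim != 3:
        raise ValueError("ensemble must be (n_samples, n_beads, 3)")
    n_samples, n_beads, _ = ens.shape
    if n_samples < 100:
        raise ValueError(f"need >= 100 samples for fluctuation matching, got {n_samples}")
    mean = ens.mean(axis=0)

    iu, ju = np.triu_indices(n_beads, k=1)
    dvec = ens[:, ju] - ens[:, iu]  # (n_samples, n_pairs, 3)
    mean_dvec = dvec.mean(axis=0)
    mean_dist = np.linalg.norm(mean_dvec, axis=1)
    # bond-projected distance fluctuation: var(n . (x_j - x_i)) with n the
    # mean bond direction — the exact harmonic (linearised) statistic, free
    # of the transverse anharmonic bias of var(|x_j - x_i|)
    nhat = mean_dvec / mean_dist[:, None]
    proj = np.einsum("spd,pd->sp", dvec, nhat)
    var_dist = proj.var(axis=0, ddof=1)

    cand = mean_dist < cutoff
    if not cand.any():
        raise ValueError("no bead pair within the hENM cutoff")
    if np.any(var_dist[cand] < rigid_sigma_floor ** 2):
        bad = np.nonzero(cand & (var_dist < rigid_sigma_floor ** 2))[0][0]
        raise ValueError(
            f"rigid ensemble: pair ({iu[bad]}, {ju[bad]}) has (near-)zero "
            "distance fluctuation; fluctuation matching is ill-posed")

    pairs = np.column_stack([iu[cand], ju[cand]])
    target = var_dist[cand]
    r0 = mean_dist[cand]
    k = np.full(len(pairs), float(k_init))

    active = np.ones(len(pairs), dtype=bool)
    residual = np.inf
    for _ in range(max_iter):
        net = SpringNetwork(pairs[active], k[active], r0[active])
        cov, _ = thermal_covariance(mean, net, temperature)
        var_model = distance_variances(mean, cov, pairs[active])
        ratio = var_model / target[active]
        residual = float(np.max(np.abs(ratio - 1.0)))
        if residual < tol:
            break
        k[active] = k[active] * ratio ** alpha
        newly_floored = active.copy()
        newly_floored[active] = k[active] < k_floor
        if newly_floored.any() and newly_floored.sum() < active.sum() - 1:
            active &= ~newly_floored
    else:
        raise HenmConvergenceError(max_iter, residual)

    pairs_out = [tuple(p) for p in pairs[active]]
    k_out = list(k[active])
    r0_out = list(r0[active])
    if backfill_sc is not None:
        have = {(min(i, j), max(i, j)) for i, j in pairs_out}
        close = mean_dist < backfill_cutoff
        for idx in np.nonzero(close)[0]:
            key = (int(iu[idx]), int(ju[idx]))
            if key not in have:
                pairs_out.append(key)
                k_out.append(float(backfill_sc))
                r0_out.append(float(mean_dist[idx]))
    return SpringNetwork(np.array(pairs_out), np.array(k_out), np.array(r0_out))


def sample_gaussian_ensemble(positions, network: SpringNetwork, temperature: float,
                             n_samples: int, rng) -> np.ndarray:
    """Draw aligned samples from the harmonic network's thermal distribution.

    Rigid-body (zero) modes are excluded, so samples fluctuate around
    ``positions`` without drifting or rotating.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    h = network_hessian(pos, network)
    w, v = np.linalg.eigh(h)
    scale = max(w.max(), 1.0)
    nonzero = w > _RIGID_TOL * scale
    n_zero = int((~nonzero).sum())
    if n_zero > 6:
        raise ValueError(
            f"network has {n_zero - 6} internal zero modes beyond the 6 rigid-body "
            "modes; it is effectively disconnected")
    amp = np.sqrt(kBT(temperature) / w[nonzero])  # nm, per mode
    coeff = rng.standard_normal((n_samples, nonzero.sum())) * amp
    disp = coeff @ v[:, nonzero].T  # (n_samples, 3N)
    return pos[None] + disp.reshape(n_samples, n, 3)
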