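"""Position-dependent lateral diffusion analysis.

Lipid diffusion is measured relative to the protein: each frame is
translated so the reference selection's center of mass (the lumenal domain
in the study protocol) sits at the origin, molecules are classified by their
time-averaged planar (XY) distance from that origin into three radial
classes (inside the ring < 3.5 nm, the TM zone 3.5-7.0 nm, and the
protein-free zone beyond 7.0 nm), and the lateral diffusion coefficient of
each species x class is obtained from the Einstein relation, D = slope / (2
dims) of the time-and-ensemble-averaged XY mean-squared displacement.
Averages and standard errors come from three equal-length trajectory blocks.

Coordinates must be unwrapped (not periodically imaged) before any MSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RadialClassSpec",
    "recenter",
    "classify_molecules",
    "msd",
    "fit_diffusion",
    "detect_plateau",
    "position_dependent_D",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RadialClassSpec:
    """Radial class boundaries (nm) and labels; ties go to the inner class."""

    boundaries: tuple = (3.5, 7.0)
    labels: tuple = ("inner", "TM", "free")

    def __post_init__(self):
        b = self.boundaries
        if any(x <= 0 for x in b) or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be positive and strictly increasing")
        if len(self.labels) != len(b) + 1:
            raise ValueError("need one more label than boundary")

    def classify(self, radius: float) -> str:
        for b, label in zip(self.boundaries, self.labels):
            if radius <= b:
                return label
        return self.labels[-1]


def recenter(positions, reference_indices, masses=None):
    """Translate every frame so the reference center of mass is at the origin.

    ``positions`` is (n_frames, n_particles, 3); the reference selection must
    be non-empty.  Any rigid global drift common to all particles cancels by
    construction.
    """
    pos = np.asarray(positions, dtype=float)
    ref = np.asarray(reference_indices)
    if ref.dtype == bool:
        ref = np.nonzero(ref)[0]
    if len(ref) == 0:
        raise ValueError("empty reference selection")
    if masses is None:
        com = pos[:, ref].mean(axis=1)
    else:
        w = np.asarray(masses, dtype=float)[ref]
        com = np.einsum("fnr,n->fr", pos[:, ref], w) / w.sum()
    return pos - com[:, None, :]


def classify_molecules(positions, spec: RadialClassSpec = RadialClassSpec()):
    """Class label per molecule from its time-averaged XY distance to origin.

    ``positions`` is (n_frames, n_molecules, 3) of recentered molecule
    reference points (grouped centers of mass).
    """
    pos = np.asarray(positions, dtype=float)
    radii = np.linalg.norm(pos[:, :, :2], axis=2).mean(axis=0)
    return np.array([spec.classify(r) for r in radii], dtype=object)


def msd(positions, molecule_indices=None, max_lag: int = None):
    """Time- and ensemble-averaged planar (XY) MSD over all time origins.

    ``positions`` (n_frames, n_molecules, 3) must be unwrapped.  Returns an
    array of length ``max_lag + 1`` (nm^2) with MSD(0) = 0.
    """
    pos = np.asarray(positions, dtype=float)[:, :, :2]
    if molecule_indices is not None:
        pos = pos[:, np.asarray(molecule_indices)]
    n = pos.shape[0]
    if max_lag is None:
        max_lag = n // 2
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} >= trajectory length {n}")
    # FFT-accelerated time average (Kubo/Wiener-Khinchin form):
    # MSD(k) = <|r(t+k)|^2 + |r(t)|^2>_t - 2 <r(t+k).r(t)>_t
    sq = (pos ** 2).sum(axis=2)  # (T, M)
    fft = np.fft.rfft(pos, n=2 * n, axis=0)
    s2 = np.fft.irfft((fft * fft.conj()).real.sum(axis=2), axis=0)[:n]
    d_ext = np.vstack([sq, np.zeros((1, sq.shape[1]))])
    q = 2.0 * sq.sum(axis=0)
    s1 = np.empty_like(s2)
    for k in range(n):
        if k:
            q = q - d_ext[k - 1] - d_ext[n - k]
        s1[k] = q / (n - k)
    curve = (s1 - 2.0 * s2 / (n - np.arange(n))[:, None]).mean(axis=1)
    curve[0] = 0.0
    return curve[: max_lag + 1]


def fit_diffusion(msd_curve, dt: float, fit_window=None, dims: int = 2) -> float:
    """Einstein-relation D = slope / (2 dims) from a least-squares line.

    ``dt`` is the frame spacing in us (so D comes out in nm^2/us); the
    default fit window spans lags from 10% to 50% of the curve.
    """
    curve = np.asarray(msd_curve, dtype=float)
    n = len(curve)
    if fit_window is None:
        fit_window = (max(1, int(0.1 * (n - 1))), max(2, int(0.5 * (n - 1))))
    lo, hi = fit_window
    if hi - lo < 1:
        raise ValueError("fit window needs at least 2 points")
    lags = np.arange(lo, hi + 1) * dt
    slope = np.polyfit(lags, curve[lo:hi + 1], 1)[0]
    return slope / (2.0 * dims)


def detect_plateau(msd_curve, dt: float, ratio_threshold: float = 0.1) -> bool:
    """Flag confined motion: the late-lag MSD slope collapses.

    Compares the slope over the last 30% of lags with the early (10-40%)
    slope; a ratio below ``ratio_threshold`` indicates a plateau (harmonic
    confinement), where the fitted D is statistically indistinguishable
    from zero.
    """
    curve = np.asarray(msd_curve, dtype=float)
    n = len(curve)
    early = fit_diffusion(curve, dt, (1, max(3, n // 20)))
    late = fit_diffusion(curve, dt, (7 * n // 10, n - 1))
    if early <= 0:
        return False
    return late / early < ratio_threshold


def position_dependent_D(
    positions,
    species,
    dt: float,
    spec: RadialClassSpec = RadialClassSpec(),
    n_blocks: int = 3,
    max_lag: int = None,
    fit_window=None,
) -> pd.DataFrame:
    """Diffusion coefficients per species x radial class with block errors.

    ``positions`` (n_frames, n_molecules, 3) are recentered, unwrapped
    molecule reference points; ``species`` labels each molecule (e.g.
    cytosolic-PL / lumenal-PL / TG); ``dt`` is the frame spacing in us.
    Classification and the MSD fit are done independently in ``n_blocks``
    equal-length blocks; the table reports mean, standard error and the
    molecule count per cell.  Classes empty in some block are reported with
    the blocks that had members (flagged in ``n_blocks_present``).
    """
    pos = np.asarray(positions, dtype=float)
    species = np.asarray(species)
    n_frames = pos.shape[0]
    if n_frames < n_blocks:
        raise ValueError("fewer frames than blocks")
    per_block = n_frames // n_blocks

    cells = {}
    for b in range(n_blocks):
        block = pos[b * per_block:(b + 1) * per_block]
        labels = classify_molecules(block, spec)
        for sp in np.unique(species):
            for cl in spec.labels:
                sel = (species == sp) & (labels == cl)
                key = (sp, cl)
                cells.setdefault(key, {"D": [], "n": []})
                if not sel.any():
                    logger.info("block %d: no %s molecules in class %s", b, sp, cl)
                    continue
                curve = msd(block, np.nonzero(sel)[0], max_lag)
                cells[key]["D"].append(fit_diffusion(curve, dt, fit_window))
                cells[key]["n"].append(int(sel.sum()))
    rows = []
    for (sp, cl), vals in cells.items():
        ds = np.array(vals["D"])
        rows.append({
            "species": sp, "class": cl,
            "D": ds.mean() if len(ds) else np.nan,
            "stderr": ds.std(ddof=1) / np.sqrt(len(ds)) if len(ds) > 1 else np.nan,
            "n_molecules": int(np.mean(vals["n"])) if vals["n"] else 0,
            "n_blocks_present": len(ds),
        })
    return pd.DataFrame(rows)
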