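"""Oil-lens morphology metrics: TG clustering, nucleation percentage,
shape anisotropy, ER-LD neck diameter, and RMSF.

TG molecules are clustered by single linkage: two molecules join the same
cluster when their minimum inter-bead distance is below 2 nm (so two oil
lenses become one the moment any two of their TG molecules approach within
the cutoff).  The nucleation percentage is the share of TG molecules in the
largest cluster.  The cluster shape is summarised by the relative shape
anisotropy

    kappa^2 = (3/2) (l1^2 + l2^2 + l3^2) / (l1 + l2 + l3)^2 - 1/2

of the mass-weighted gyration-tensor eigenvalues l_i: 0 for a sphere, 0.25
for a thin disc, 1 for a line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "ClusterResult",
    "LensMetrics",
    "cluster_tg",
    "nucleation_percentage",
    "anisotropy",
    "neck_diameter",
    "rmsf",
    "metrics_timeseries",
]


@dataclass
class ClusterResult:
    """Single-linkage TG cluster assignment for one frame."""

    labels: np.ndarray  # (n_molecules,) cluster id per TG molecule
    sizes: np.ndarray  # (n_clusters,) molecule counts
    largest_cluster_id: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class LensMetrics:
    nucleation_percentage: float
    anisotropy: float
    neck_diameter: float | None = None
    frame_index: int | None = None


def _wrap(pos, box):
    return np.mod(pos, box)


def cluster_tg(bead_positions, molecule_ids, cutoff: float = 2.0, box=None) -> ClusterResult:
    """Single-linkage clustering of TG molecules.

    Parameters
    ----------
    bead_positions : (n_beads, 3) nm — all TG beads in the frame
    molecule_ids : (n_beads,) molecule label per bead
    cutoff : nm — two molecules are linked if any inter-bead distance < cutoff
    box : optional (3,) periodic box; minimum-image distances if given
    """
    pos = np.asarray(bead_positions, dtype=float)
    molecule_ids = np.asarray(molecule_ids)
    if len(pos) == 0:
        raise ValueError("no TG beads to cluster")
    mols, mol_idx = np.unique(molecule_ids, return_inverse=True)
    n = len(mols)
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(_wrap(pos, box), boxsize=box)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        i = mol_idx[pairs[:, 0]]
        j = mol_idx[pairs[:, 1]]
        keep = i != j
        i, j = i[keep], j[keep]
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    return ClusterResult(labels=labels, sizes=sizes,
                         largest_cluster_id=int(np.argmax(sizes)))


def nucleation_percentage(result: ClusterResult, n_total: int) -> float:
    """Percent of TG molecules belonging to the largest cluster."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    return 100.0 * float(result.sizes.max()) / n_total


def gyration_eigenvalues(positions, masses=None):
    """Eigenvalues (ascending, nm^2) of the mass-weighted gyration tensor."""
    pos = np.asarray(positions, dtype=float)
    if masses is None:
        masses = np.ones(len(pos))
    masses = np.asarray(masses, dtype=float)
    com = np.average(pos, axis=0, weights=masses)
    d = pos - com
    s = np.einsum("n,ni,nj->ij", masses, d, d) / masses.sum()
    return np.linalg.eigvalsh(s)


def anisotropy(positions, masses=None) -> float:
    """Relative shape anisotropy kappa^2 of one cluster, in [0, 1]."""
    lam = gyration_eigenvalues(positions, masses)
    tr = lam.sum()
    if tr <= 0:
        raise ValueError("degenerate cluster: all beads coincident")
    return float(1.5 * np.sum(lam ** 2) / tr ** 2 - 0.5)


def neck_diameter(tip_positions, protein_positions=None, axis=None) -> float:
    """ER-LD neck diameter from the terminal TM tip beads, nm.

    The diameter is twice the mean in-plane radial distance of the tip beads
    from the complex axis.  The axis defaults to the principal (symmetry)
    axis of the protein beads — the gyration-tensor eigenvector with the
    smallest eigenvalue of an oblate ring — through their center of mass.
    """
    tips = np.asarray(tip_positions, dtype=float)
    if len(tips) < 3:
        raise ValueError("need at least 3 tip beads")
    ref = np.asarray(protein_positions, dtype=float) if protein_positions is not None else tips
    com = ref.mean(axis=0)
    if axis is None:
        d = ref - com
        s = d.T @ d / len(d)
        w, v = np.linalg.eigh(s)
        axis = v[:, 0]
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rel = tips - com
    radial = rel - np.outer(rel @ axis, axis)
    return 2.0 * float(np.linalg.norm(radial, axis=1).mean())


def rmsf(ensemble) -> np.ndarray:
    """Per-bead root-mean-square fluctuation of an aligned ensemble, nm.

    ``ensemble`` is (n_samples, n_beads, 3), rigid-body aligned to its mean.
    """
    ens = np.asarray(ensemble, dtype=float)
    if ens.ndim != 3 or ens.shape[0] < 2:
        raise ValueError("need an (n_samples, n_beads, 3) ensemble with >= 2 samples")
    mean = ens.mean(axis=0)
    d = ens - mean
    return np.sqrt((d ** 2).sum(axis=2).mean(axis=0))


@dataclass
class EventTags:
    """Heuristic growth-mechanism annotations for a nucleation time series."""

    coalescence_frames: list = field(default_factory=list)
    ripening: bool = False
    jump_threshold: float = 10.0
    ripening_slope: float = 0.5


def metrics_timeseries(
    frames,
    tg_selector,
    cutoff: float = 2.0,
    tip_selector=None,
    protein_selector=None,
    jump_threshold: float = 10.0,
    ripening_slope: float = 0.5,
) -> tuple[pd.DataFrame, EventTags]:
    """Per-frame lens metrics plus rule-based event classification.

    ``frames`` iterates over frame objects; ``tg_selector(frame)`` must return
    ``(bead_positions, molecule_ids, box_or_None)`` for the TG beads, and the
    optional ``tip_selector`` / ``protein_selector`` return tip and protein
    bead positions for the neck-diameter column.

    A step increase in nucleation percentage larger than ``jump_threshold``
    points between consecutive frames is tagged a coalescence candidate;
    sustained slow growth (positive mean slope below the jump threshold,
    exceeding ``ripening_slope`` points/frame over the last half) is tagged
    Ostwald-ripening-like.  These are annotations only.
    """
    rows = []
    for fi, frame in enumerate(frames):
        pos, mols, box = tg_selector(frame)
        res = cluster_tg(pos, mols, cutoff=cutoff, box=box)
        n_total = len(np.unique(mols))
        largest_mask = res.labels[np.unique(np.asarray(mols), return_inverse=True)[1]] \
            == res.largest_cluster_id
        kappa = anisotropy(np.asarray(pos)[largest_mask]) if largest_mask.sum() >= 2 else 0.0
        neck = None
        if tip_selector is not None:
            tips = tip_selector(frame)
            prot = protein_selector(frame) if protein_selector is not None else None
            neck = neck_diameter(tips, prot)
        rows.append({"frame_index": fi,
                     "nucleation_percentage": nucleation_percentage(res, n_total),
                     "anisotropy": kappa,
                     "neck_diameter": neck})
    df = pd.DataFrame(rows)
    tags = EventTags(jump_threshold=jump_threshold, ripening_slope=ripening_slope)
    nuc = df["nucleation_percentage"].to_numpy()
    if len(nuc) >= 2:
        jumps = np.diff(nuc)
        tags.coalescence_frames = list(np.nonzero(jumps > jump_threshold)[0] + 1)
        half = nuc[len(nuc) // 2:]
        if len(half) >= 2 and not tags.coalescence_frames:
            slope = np.polyfit(np.arange(len(half)), half, 1)[0]
            tags.ripening = 0 < slope and slope * len(half) > ripening_slope * len(half) \
                and slope < jump_threshold
    return df, tags
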