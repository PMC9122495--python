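"""Per-residue coordination-number statistics against PL and TG.

For each protein residue the side-chain group acts as a probe, and its
coordination number with a lipid species M is

    s_M = sum_a [1 - (r_a/r0)^6] / [1 - (r_a/r0)^12]

over all reduced-resolution groups ``a`` of species M, where ``r_a`` is the
probe-group distance (minimum image).  The summand is evaluated through the
algebraically equivalent, singularity-free form 1/(1 + (r/r0)^6).  The
per-molecule normalisation ||s|| = s / n_molecules gives a concentration-
independent preference, and the per-atom normalisation ||s_A|| = s / n_groups
compares group kinds (12 tail vs 1 glycerol group per TG).  Block averaging
over equal-length trajectory thirds provides standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import GroupedFrame

__all__ = [
    "SwitchingParams",
    "switching_value",
    "coordination_number",
    "normalize",
    "residue_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters; ``r0`` in nm (default 0.4)."""

    r0: float = 0.4

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


def switching_value(r, params: SwitchingParams = SwitchingParams()):
    """Evaluate [1-(r/r0)^6]/[1-(r/r0)^12] == 1/(1+(r/r0)^6).

    Strictly decreasing in r; 1 at r=0 and 1/2 at r=r0.  Accepts scalars or
    arrays; negative distances are rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    x = r / params.r0
    out = 1.0 / (1.0 + x ** 6)
    return float(out) if out.ndim == 0 else out


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


_TARGET_SELECTORS = {
    "PL": lambda f: f.molecule_kind == "POPC",
    "TG": lambda f: f.molecule_kind == "TG",
    "TG-glycerol": lambda f: (f.molecule_kind == "TG") & (f.group_kind == "glycerol"),
    "TG-tail": lambda f: (f.molecule_kind == "TG") & (f.group_kind == "tail"),
}


def coordination_number(
    probe,
    frame: GroupedFrame,
    target_kind: str,
    params: SwitchingParams = SwitchingParams(),
    cutoff: float | None = None,
):
    """Coordination number of one probe position with all groups of a species.

    ``target_kind`` is one of PL, TG, TG-glycerol, TG-tail.  Distances use the
    minimum-image convention in the frame's periodic box.  ``cutoff`` (nm)
    optionally truncates the sum for speed; the switching function decays as
    (r0/r)^6 so the default is no cutoff.
    """
    try:
        mask = _TARGET_SELECTORS[target_kind](frame)
    except KeyError:
        raise ValueError(f"unknown target kind {target_kind!r}") from None
    if not mask.any():
        raise ValueError(f"empty target selection {target_kind!r} in frame")
    d = _minimum_image(frame.positions[mask] - np.asarray(probe, dtype=float), frame.box)
    r = np.linalg.norm(d, axis=1)
    if cutoff is not None:
        r = r[r < cutoff]
    return float(np.sum(switching_value(r, params)))


def normalize(s: float, denom: int, mode: str = "per_molecule") -> float:
    """Normalise a coordination number by a molecule or grouped-atom count."""
    if mode not in ("per_molecule", "per_atom"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if denom == 0:
        raise ValueError("normalisation denominator is zero")
    return s / denom


def _frame_residue_values(frame: GroupedFrame, params, cutoff):
    probe_mask = (frame.molecule_kind == "residue") & (frame.group_kind == "sidechain")
    residues = frame.molecule_id[probe_mask]
    probes = frame.positions[probe_mask]
    vals = {}
    for tk in ("PL", "TG", "TG-glycerol", "TG-tail"):
        mask = _TARGET_SELECTORS[tk](frame)
        if not mask.any():
            vals[tk] = np.zeros(len(probes))
            continue
        tpos = frame.positions[mask]
        d = probes[:, None, :] - tpos[None, :, :]
        d = _minimum_image(d, frame.box)
        r = np.sqrt((d * d).sum(axis=2))
        sw = switching_value(r, params)
        if cutoff is not None:
            sw = np.where(r < cutoff, sw, 0.0)
        vals[tk] = sw.sum(axis=1)
    return residues, vals


def residue_profile(
    frames: Sequence[GroupedFrame],
    params: SwitchingParams = SwitchingParams(),
    n_blocks: int = 3,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Time-averaged per-residue coordination profile with block errors.

    Returns one row per residue with columns ``s_PL``, ``s_TG``, their
    per-molecule normalisations ``s_per_molecule_*``, the per-atom TG-part
    normalisations ``s_per_atom_glycerol`` / ``s_per_atom_tail``, and a
    ``*_err`` standard error for each, computed over ``n_blocks`` equal-length
    trajectory blocks (trailing frames beyond a whole multiple are dropped
    with a warning).
    """
    frames = list(frames)
    if len(frames) < n_blocks:
        raise ValueError(f"need at least {n_blocks} frames, got {len(frames)}")
    per_block = len(frames) // n_blocks
    dropped = len(frames) - per_block * n_blocks
    if dropped:
        logger.warning("dropping %d trailing frames not filling a block", dropped)
        frames = frames[: per_block * n_blocks]

    f0 = frames[0]
    n_pl = f0.molecule_count("POPC")
    n_tg = f0.molecule_count("TG")
    n_tg_gly = int(((f0.molecule_kind == "TG") & (f0.group_kind == "glycerol")).sum())
    n_tg_tail = int(((f0.molecule_kind == "TG") & (f0.group_kind == "tail")).sum())

    block_means = []  # per block: residues -> dict of statistics
    residues_ref = None
    for b in range(n_blocks):
        acc = None
        for frame in frames[b * per_block:(b + 1) * per_block]:
            residues, vals = _frame_residue_values(frame, params, cutoff)
            if residues_ref is None:
                residues_ref = residues
            elif not np.array_equal(residues, residues_ref):
                raise ValueError("residue identities change between frames")
            if acc is None:
                acc = {k: v.astype(float).copy() for k, v in vals.items()}
            else:
                for k, v in vals.items():
                    acc[k] += v
        block = {k: v / per_block for k, v in acc.items()}
        block_means.append(block)

    def stack(key):
        return np.stack([b[key] for b in block_means])  # (n_blocks, n_res)

    cols = {"residue_index": residues_ref}
    stats = {
        "s_PL": stack("PL"),
        "s_TG": stack("TG"),
        "s_per_molecule_PL": stack("PL") / max(n_pl, 1) if n_pl else stack("PL") * np.nan,
        "s_per_molecule_TG": stack("TG") / max(n_tg, 1) if n_tg else stack("TG") * np.nan,
        "s_per_atom_glycerol": stack("TG-glycerol") / max(n_tg_gly, 1)
        if n_tg_gly else stack("TG-glycerol") * np.nan,
        "s_per_atom_tail": stack("TG-tail") / max(n_tg_tail, 1)
        if n_tg_tail else stack("TG-tail") * np.nan,
    }
    for name, blocks in stats.items():
        cols[name] = blocks.mean(axis=0)
        cols[name + "_err"] = blocks.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return pd.DataFrame(cols)
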