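"""Archives for grouped frames and internal trajectories.

Grouped-frame sequences go to a single columnar parquet file (one table with
a frame column: frame, molecule_id, molecule_kind, group_label, group_kind,
x/y/z in nm, n_member_atoms, group_mass) plus the boxes; a pseudo-PDB writer
emits one HETATM record per group for quick visualisation.  Simulator
trajectories use a compressed .npz archive.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .mapping import GroupedFrame

__all__ = [
    "write_grouped_frames",
    "read_grouped_frames",
    "write_pseudo_pdb",
    "write_trajectory",
    "read_trajectory",
]


def grouped_to_dataframe(frames) -> pd.DataFrame:
    parts = []
    for fi, f in enumerate(frames):
        parts.append(pd.DataFrame({
            "frame": fi,
            "molecule_id": f.molecule_id,
            "molecule_kind": f.molecule_kind.astype(str),
            "group_label": f.group_label.astype(str),
            "group_kind": f.group_kind.astype(str),
            "x": f.positions[:, 0], "y": f.positions[:, 1], "z": f.positions[:, 2],
            "n_member_atoms": f.n_member_atoms,
            "group_mass": f.group_mass if f.group_mass is not None else np.nan,
        }))
    return pd.concat(parts, ignore_index=True)


def write_grouped_frames(frames, path: str) -> None:
    """Write a GroupedFrame sequence to ``path`` (.parquet) + a box sidecar."""
    df = grouped_to_dataframe(frames)
    df.to_parquet(path, index=False)
    boxes = {str(fi): list(map(float, f.box)) for fi, f in enumerate(frames)}
    with open(path + ".boxes.json", "w") as fh:
        json.dump(boxes, fh)


def read_grouped_frames(path: str) -> list:
    df = pd.read_parquet(path)
    with open(path + ".boxes.json") as fh:
        boxes = json.load(fh)
    frames = []
    for fi, sub in df.groupby("frame", sort=True):
        frames.append(GroupedFrame(
            sub["molecule_id"].to_numpy(),
            sub["molecule_kind"].to_numpy(dtype=object),
            sub["group_label"].to_numpy(dtype=object),
            sub["group_kind"].to_numpy(dtype=object),
            sub[["x", "y", "z"]].to_numpy(),
            sub["n_member_atoms"].to_numpy(dtype=int),
            np.array(boxes[str(fi)]),
            sub["group_mass"].to_numpy(),
        ))
    return frames


def write_pseudo_pdb(frame: GroupedFrame, path: str) -> None:
    """One HETATM record per group (positions in A), for visual checks only."""
    with open(path, "w") as fh:
        fh.write(f"CRYST1{frame.box[0] * 10:9.3f}{frame.box[1] * 10:9.3f}"
                 f"{frame.box[2] * 10:9.3f}  90.00  90.00  90.00 P 1\n")
        for i in range(len(frame)):
            name = str(frame.group_label[i])[:4].upper()
            res = str(frame.molecule_kind[i])[:3].upper()
            x, y, z = frame.positions[i] * 10
            fh.write(f"HETATM{i + 1:5d} {name:<4s}{res:>4s} A"
                     f"{int(frame.molecule_id[i]) % 10000:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
        fh.write("END\n")


def write_trajectory(result, path: str) -> None:
    """Save a SimulationResult's frames and logs to a .npz archive."""
    payload = {"positions": result.positions, "steps": result.steps}
    for k, v in result.log.items():
        payload[f"log_{k}"] = np.asarray(v)
    np.savez_compressed(path, **payload)


def read_trajectory(path: str) -> dict:
    with np.load(path) as arc:
        out = {"positions": arc["positions"], "steps": arc["steps"], "log": {}}
        for k in arc.files:
            if k.startswith("log_"):
                out["log"][k[4:]] = arc[k]
    return out
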