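"""Tabular input/output: trajectories, snapshots, distributions, clusters.

All tabular files are plain CSV with 0-based (row, col) coordinates.
Trajectories are written long-form (synapse_id, step, size); snapshots as
one (row, col) pair per occupied site.  A compact ``.npz`` container is
available for large ensembles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import EnsembleTrajectory, LatticeState
from .params import KineticParams, NeighborSpec

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_trajectory_npz",
    "read_trajectory_npz",
    "write_snapshot_csv",
    "read_snapshot_csv",
]


def write_trajectory_csv(traj: EnsembleTrajectory, path) -> None:
    sizes = traj.sizes
    n_syn, n_t = sizes.shape
    df = pd.DataFrame(
        {
            "synapse_id": np.repeat(np.arange(n_syn), n_t),
            "step": np.tile(np.arange(n_t), n_syn),
            "size": sizes.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# model={traj.params.model} lambda_on={traj.params.lambda_on} "
            f"lambda_off={traj.params.lambda_off} alpha={traj.params.alpha} "
            f"beta={traj.params.beta} dt={traj.params.dt} "
            f"neighbors={traj.spec.mode} rows={traj.rows} cols={traj.cols} "
            f"seed={traj.master_seed}\n"
        )
        df.to_csv(fh, index=False)


def read_trajectory_csv(path) -> np.ndarray:
    """Read a long-form trajectory CSV back into an (n_synapses, T) array."""
    df = pd.read_csv(path, comment="#")
    n_syn = df["synapse_id"].nunique()
    n_t = df["step"].nunique()
    out = np.full((n_syn, n_t), -1, dtype=np.int64)
    out[df["synapse_id"].to_numpy(), df["step"].to_numpy()] = df["size"].to_numpy()
    if (out < 0).any():
        raise ValueError(f"trajectory file {path} has missing (synapse, step) entries")
    return out


def write_trajectory_npz(traj: EnsembleTrajectory, path) -> None:
    np.savez_compressed(
        path,
        sizes=traj.sizes,
        master_seed=traj.master_seed,
        rows=traj.rows,
        cols=traj.cols,
        **{f"snapshot_{t}": g for t, g in traj.snapshots.items()},
    )


def read_trajectory_npz(path):
    """Returns (sizes, snapshots dict, master_seed)."""
    with np.load(path) as data:
        sizes = data["sizes"]
        seed = int(data["master_seed"])
        snaps = {
            int(k.split("_", 1)[1]): data[k]
            for k in data.files
            if k.startswith("snapshot_")
        }
    return sizes, snaps, seed


def write_snapshot_csv(state: LatticeState, path) -> None:
    """One occupied site per line as 0-based (row, col)."""
    coords = state.occupied_coords()
    rows, cols = state.shape
    with open(path, "w") as fh:
        fh.write(f"# rows={rows} cols={cols}\n")
        pd.DataFrame(coords, columns=["row", "col"]).to_csv(fh, index=False)


def read_snapshot_csv(path) -> LatticeState:
    header = Path(path).read_text().splitlines()[0]
    if not header.startswith("#"):
        raise ValueError(f"snapshot file {path} lacks its '# rows= cols=' header")
    meta = dict(tok.split("=") for tok in header[1:].split())
    rows, cols = int(meta["rows"]), int(meta["cols"])
    df = pd.read_csv(path, comment="#")
    occ = np.zeros((rows, cols), dtype=bool)
    if len(df):
        occ[df["row"].to_numpy(), df["col"].to_numpy()] = True
    return LatticeState(occ)
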