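"""HDF5/JSON export of trajectories and PDE snapshots.

Arrays go to HDF5 with grid and run metadata as attributes; a JSON manifest
lists the datasets so archives are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

__all__ = ["save_particles_hdf5", "save_solution_hdf5"]


def save_particles_hdf5(times: np.ndarray, snapshots: list, path, *,
                        seed: int | None = None, L: float | None = None) -> None:
    """Write particle trajectory snapshots (times, positions) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=np.asarray(times, dtype=float))
        g = f.create_group("positions")
        for j, X in enumerate(snapshots):
            g.create_dataset(f"{j:05d}", data=np.asarray(X))
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if L is not None:
            f.attrs["L"] = float(L)
        f.attrs["n_snapshots"] = len(snapshots)
    manifest = {
        "file": path.name,
        "times": np.asarray(times, dtype=float).tolist(),
        "n_snapshots": len(snapshots),
        "seed": seed,
    }
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def save_solution_hdf5(solution, path) -> None:
    """Write a PDE solution (snapshots + conservation series) to HDF5."""
    path = Path(path)
    grid = solution.snapshots[0].grid
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=solution.times)
        f.create_dataset("mass_series", data=solution.mass_series)
        f.create_dataset("min_series", data=solution.min_series)
        g = f.create_group("fields")
        for j, snap in enumerate(solution.snapshots):
            g.create_dataset(f"{j:05d}", data=snap.values)
        f.attrs["equation"] = solution.equation_tag
        f.attrs["L"] = grid.L
        f.attrs["n"] = grid.n
        f.attrs["d"] = grid.d
        f.attrs["blew_up"] = bool(solution.blew_up)
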