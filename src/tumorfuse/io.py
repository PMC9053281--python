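"""Plain-text persistence for trajectories and tables.

Spatial trajectories go to long-format CSV (one row per node per save
time: ``t, x, c, n, v``); float64 values are written at full precision
so a round-trip reproduces the arrays exactly.  An optional binary
container (NPZ) is offered for bulk storage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid1D, SpatialState

__all__ = ["save_states_csv", "load_states_csv", "save_states_npz", "load_states_npz"]


def save_states_csv(states: list[SpatialState], grid: Grid1D, path: str | Path) -> None:
    frames = []
    for s in states:
        frames.append(
            pd.DataFrame({"t": s.t, "x": grid.x, "c": s.c, "n": s.n, "v": s.v})
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_states_csv(path: str | Path) -> tuple[list[SpatialState], Grid1D]:
    df = pd.read_csv(path, float_precision="round_trip")
    states = []
    grid = None
    for t, g in df.groupby("t", sort=True):
        x = g["x"].to_numpy()
        if grid is None:
            grid = Grid1D(float(x[-1]), len(x))
        states.append(
            SpatialState(
                g["c"].to_numpy(), g["n"].to_numpy(), g["v"].to_numpy(), t=float(t)
            )
        )
    if grid is None:
        raise ValueError(f"no states found in {path}")
    return states, grid


def save_states_npz(states: list[SpatialState], grid: Grid1D, path: str | Path) -> None:
    np.savez_compressed(
        path,
        x=grid.x,
        t=np.array([s.t for s in states]),
        c=np.stack([s.c for s in states]),
        n=np.stack([s.n for s in states]),
        v=np.stack([s.v for s in states]),
    )


def load_states_npz(path: str | Path) -> tuple[list[SpatialState], Grid1D]:
    with np.load(path) as data:
        grid = Grid1D(float(data["x"][-1]), len(data["x"]))
        states = [
            SpatialState(data["c"][k], data["n"][k], data["v"][k], t=float(tk))
            for k, tk in enumerate(data["t"])
        ]
    return states, grid
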