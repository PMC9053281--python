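"""Uniform 1-D spatial grids and tissue state containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid1D:
    """Uniform grid on ``[0, L]`` with ``n_nodes`` nodes.

    Lengths are in millimetres throughout the public interface (times in
    months); nothing in the numerics depends on the unit choice.
    """

    length: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"grid length must be positive, got {self.length}")
        if self.n_nodes < 2:
            raise ValueError(f"need at least 2 nodes, got {self.n_nodes}")

    @property
    def dx(self) -> float:
        return self.length / (self.n_nodes - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)


@dataclass
class SpatialState:
    """Tissue state at one instant: tumor density ``c``, oxygen ``n``,
    functional vasculature ``v`` (all normalized to carrying capacity,
    values in ``[0, 1]``), on a shared grid; ``t`` in months."""

    c: np.ndarray
    n: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (self.c.shape == self.n.shape == self.v.shape):
            raise ValueError("c, n, v must share one grid")

    def validate(self, grid: Grid1D, tol: float = 1e-6) -> None:
        """Check shape compatibility, finiteness and the [0, 1] range."""
        for name, arr in (("c", self.c), ("n", self.n), ("v", self.v)):
            if arr.shape != (grid.n_nodes,):
                raise ValueError(
                    f"{name} has shape {arr.shape}, grid has {grid.n_nodes} nodes"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if arr.min() < -tol or arr.max() > 1.0 + tol:
                raise ValueError(
                    f"{name} outside [0, 1] beyond tolerance: "
                    f"min={arr.min():.3g}, max={arr.max():.3g}"
                )

    def copy(self) -> "SpatialState":
        return SpatialState(self.c.copy(), self.n.copy(), self.v.copy(), self.t)
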