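"""Discretized probability densities over clinical-output space.

A :class:`PdfGrid` holds a non-negative density sampled on a tensor grid
of 1 or 2 (in principle any number of) uniformly spaced axes.  Densities
are normalized in the Riemann sense: ``values.sum() * cell_volume == 1``.
All fusion-rule algebra (products, expectations, modes, marginals) is
implemented against this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PdfGrid"]

_NORM_TOL = 1e-9


def _check_axis(axis: np.ndarray, i: int) -> None:
    if axis.ndim != 1 or axis.size < 1:
        raise ValueError(f"axis {i} must be a 1-D vector")
    if axis.size > 1:
        d = np.diff(axis)
        if np.any(d <= 0):
            raise ValueError(f"axis {i} must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-8, atol=0.0):
            raise ValueError(f"axis {i} must be uniformly spaced")


@dataclass
class PdfGrid:
    """Density on a tensor grid.

    Parameters
    ----------
    axes
        Per-dimension coordinate vectors (strictly increasing, uniform).
    values
        Density array with shape ``tuple(len(a) for a in axes)``; must be
        non-negative and finite.
    normalized
        Whether ``values`` integrates (Riemann sum x cell volume) to 1.
    axis_names
        Optional labels, e.g. ``("IW", "TS")``.
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    normalized: bool = False
    axis_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        for i, a in enumerate(self.axes):
            _check_axis(a, i)
        expected = tuple(a.size for a in self.axes)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match axes {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("density must be non-negative")
        if self.axis_names is not None and len(self.axis_names) != len(self.axes):
            raise ValueError("axis_names length must match the number of axes")
        if self.normalized:
            total = self.values.sum() * self.cell_volume
            if abs(total - 1.0) > _NORM_TOL:
                raise ValueError(
                    f"density declared normalized but integrates to {total!r}"
                )

    # -- geometry ----------------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def spacings(self) -> tuple[float, ...]:
        return tuple(
            float(a[1] - a[0]) if a.size > 1 else 1.0 for a in self.axes
        )

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacings))

    def same_axes(self, other: "PdfGrid") -> bool:
        return self.ndim == other.ndim and all(
            a.shape == b.shape and np.array_equal(a, b)
            for a, b in zip(self.axes, other.axes)
        )

    # -- normalization -----------------------------------------------------

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_volume)

    def normalize(self) -> "PdfGrid":
        """Return a normalized copy; raises on zero total mass."""
        total = self.total_mass()
        if total <= 0:
            raise ValueError("cannot normalize a density with zero total mass")
        return PdfGrid(
            self.axes, self.values / total, normalized=True, axis_names=self.axis_names
        )

    # -- summaries (thin wrappers; the fusion module hosts the full set) ---

    def marginal(self, axis: int) -> "PdfGrid":
        """Marginal density on one axis (Riemann sum over the others)."""
        if not 0 <= axis < self.ndim:
            raise ValueError(f"axis {axis} out of range for ndim {self.ndim}")
        other = tuple(i for i in range(self.ndim) if i != axis)
        vol_other = float(
            np.prod([self.spacings[i] for i in other])
        ) if other else 1.0
        vals = self.values.sum(axis=other) * vol_other if other else self.values.copy()
        names = (self.axis_names[axis],) if self.axis_names else None
        return PdfGrid(
            (self.axes[axis],), vals, normalized=self.normalized, axis_names=names
        )

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per grid cell, axis coordinates
        followed by the density value."""
        names = self.axis_names or tuple(f"axis{i}" for i in range(self.ndim))
        mesh = np.meshgrid(*self.axes, indexing="ij")
        data = {name: m.ravel() for name, m in zip(names, mesh)}
        data["density"] = self.values.ravel()
        return pd.DataFrame(data)

    def save(self, csv_path: str | Path) -> None:
        """Write the long-format CSV plus a JSON sidecar with the axes.

        The sidecar stores the exact float64 axis values (hex encoded) so
        the round-trip is bit-exact.
        """
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        names = self.axis_names or tuple(f"axis{i}" for i in range(self.ndim))
        meta = {
            "axis_names": list(names),
            "axes_hex": [[x.hex() for x in map(float, a)] for a in self.axes],
            "normalized": bool(self.normalized),
            "shape": list(self.values.shape),
            "values_hex": [float(x).hex() for x in self.values.ravel()],
        }
        csv_path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, csv_path: str | Path) -> "PdfGrid":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        axes = tuple(
            np.array([float.fromhex(h) for h in ah]) for ah in meta["axes_hex"]
        )
        values = np.array([float.fromhex(h) for h in meta["values_hex"]]).reshape(
            meta["shape"]
        )
        return cls(
            axes,
            values,
            normalized=meta["normalized"],
            axis_names=tuple(meta["axis_names"]),
        )
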