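"""Model-derived and data-derived densities and their Bayesian fusion.

The fusion rule states that the posterior over clinical outputs given
both the modelable state and the unmodelable variables is proportional
to the product of two densities over the same output space:

    p(Y | x_m, x_u)  ∝  p(Y | x_m) · p(Y | x_u)

``p(Y | x_m)`` comes from a mechanistic-model parameter sweep (here a
tolerance-box estimator over Fisher-Kolmogorov outcomes); ``p(Y | x_u)``
comes from a Gaussian-product kernel density estimate over a patient
ensemble, conditioned on the patient's unmodelables.  Silverman's rule
of thumb sets the per-dimension kernel bandwidths:

    h_i = sigma_i · [4 / ((d + 2) n)]^(1 / (d + 4))

with ``sigma_i`` the sample standard deviation of the i-th variate,
``d`` the total dimension and ``n`` the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid1D
from .glioma import FrontError, infiltration_width, simulate_fk_batch, tumor_size
from .pdfgrid import PdfGrid

__all__ = [
    "Bandwidths",
    "IncompatibleEvidenceError",
    "silverman_bandwidths",
    "sweep_lattice",
    "fk_sweep_outcomes",
    "tolerance_box_pdf",
    "fk_model_pdf",
    "gaussian_kde_conditional",
    "kde_conditioned_pdf",
    "fuse_pdfs",
    "pdf_expected_value",
    "pdf_modes",
    "effective_variance",
    "build_output_grid",
]


class IncompatibleEvidenceError(ValueError):
    """The two densities have disjoint supports: their product is zero
    everywhere and carries no information.  No silent fallback."""


@dataclass(frozen=True)
class Bandwidths:
    """Per-dimension kernel bandwidths (same units as each variate)."""

    h: np.ndarray
    d: int
    n_obs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))
        if np.any(self.h <= 0):
            raise ValueError("bandwidths must be positive")


def silverman_bandwidths(data) -> Bandwidths:
    """Silverman rule-of-thumb bandwidths for an ``(n_obs, d)`` data matrix.

    Raises if fewer than two observations or if any column has zero
    sample standard deviation (the rule degenerates).
    """
    if isinstance(data, pd.DataFrame):
        columns = list(data.columns)
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        columns = list(range(mat.shape[1]))
    n_obs, d = mat.shape
    if n_obs < 2:
        raise ValueError(f"need at least 2 observations, got {n_obs}")
    sigma = mat.std(axis=0, ddof=1)
    for name, s in zip(columns, sigma):
        if s <= 0:
            raise ValueError(f"column {name!r} has zero variance; bandwidth undefined")
    factor = (4.0 / ((d + 2) * n_obs)) ** (1.0 / (d + 4))
    return Bandwidths(h=sigma * factor, d=d, n_obs=n_obs)


# ---------------------------------------------------------------------------
# model-derived pdf: FK sweep + tolerance box
# ---------------------------------------------------------------------------

def sweep_lattice(
    ranges: dict[str, tuple[float, float]], resolution: dict[str, int] | int
) -> dict[str, np.ndarray]:
    """Cartesian lattice over parameter ranges, flattened to 1-D arrays.

    ``ranges`` maps parameter name to ``(low, high)``; ``resolution`` is
    the per-axis point count (shared integer or per-name dict).
    """
    names = list(ranges)
    axes = []
    for name in names:
        low, high = ranges[name]
        if high < low:
            raise ValueError(f"range for {name} has high < low")
        r = resolution[name] if isinstance(resolution, dict) else resolution
        if r < 1:
            raise ValueError("sweep resolution must be >= 1 per axis")
        axes.append(np.linspace(low, high, r) if r > 1 else np.array([(low + high) / 2.0]))
    mesh = np.meshgrid(*axes, indexing="ij")
    return {name: m.ravel() for name, m in zip(names, mesh)}


def fk_sweep_outcomes(
    c_at_t0: np.ndarray,
    sweep_ranges: dict[str, tuple[float, float]],
    sweep_resolution: dict[str, int] | int,
    grid: Grid1D,
    tps: Sequence[float],
) -> np.ndarray:
    """Run the FK model from ``c_at_t0`` over the (D, b) lattice and
    extract (IW, TS) at every prediction time.

    Returns an array of shape ``(len(tps), n_sweep, 2)``; sweep points
    whose front is undefined at some time carry NaN there.
    """
    lattice = sweep_lattice(sweep_ranges, sweep_resolution)
    if set(lattice) != {"D", "b"}:
        raise ValueError("FK sweep ranges must cover exactly D and b")
    profiles = simulate_fk_batch(c_at_t0, lattice["D"], lattice["b"], grid, tps)
    n_tp, P = profiles.shape[:2]
    out = np.full((n_tp, P, 2), np.nan)
    for k in range(n_tp):
        for p in range(P):
            try:
                out[k, p, 0] = infiltration_width(profiles[k, p], grid)
                out[k, p, 1] = tumor_size(profiles[k, p], grid)
            except FrontError:
                pass
    return out


def tolerance_box_pdf(
    outcomes: np.ndarray,
    output_axes: tuple[np.ndarray, np.ndarray],
    tolerance_alpha: float = 0.05,
) -> PdfGrid:
    """Density over the output grid from sweep outcomes via the relative
    tolerance box.

    The density at a grid point ``y* = (IW*, TS*)`` is proportional to
    the number of sweep outcomes falling inside the box
    ``(1 - a) y* < y < (1 + a) y*`` componentwise, then normalized over
    the grid.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    outcomes = outcomes[np.all(np.isfinite(outcomes), axis=-1)]
    if outcomes.size == 0:
        raise ValueError("no valid sweep outcomes: cannot build the model pdf")
    if not 0 < tolerance_alpha < 1:
        raise ValueError("tolerance_alpha must be in (0, 1)")
    a = tolerance_alpha
    indicators = []
    for dim, axis in enumerate(output_axes):
        g = np.asarray(axis, dtype=float)[:, None]
        y = outcomes[None, :, dim]
        indicators.append(((1.0 - a) * g < y) & (y < (1.0 + a) * g))
    counts = indicators[0].astype(float) @ indicators[1].astype(float).T
    pdf = PdfGrid(tuple(output_axes), counts, axis_names=("IW", "TS"))
    if pdf.total_mass() <= 0:
        raise ValueError(
            "no sweep outcome falls inside any tolerance box on this grid; "
            "extend the output grid to cover the sweep outcomes"
        )
    return pdf.normalize()


def fk_model_pdf(
    c_at_t0: np.ndarray,
    sweep_ranges: dict[str, tuple[float, float]],
    sweep_resolution: dict[str, int] | int,
    grid: Grid1D,
    tp: float,
    output_axes: tuple[np.ndarray, np.ndarray],
    tolerance_alpha: float = 0.05,
) -> PdfGrid:
    """Model-derived pdf over (IW, TS) at prediction time ``tp``."""
    if tp <= 0:
        raise ValueError(f"prediction time must be positive, got {tp}")
    outcomes = fk_sweep_outcomes(c_at_t0, sweep_ranges, sweep_resolution, grid, [tp])
    return tolerance_box_pdf(outcomes[0], output_axes, tolerance_alpha)


# ---------------------------------------------------------------------------
# data-derived pdf: conditional Gaussian-product KDE
# ---------------------------------------------------------------------------

def gaussian_kde_conditional(
    data: np.ndarray,
    cond_values: Sequence[float],
    output_axes: tuple[np.ndarray, ...],
    axis_names: tuple[str, ...] | None = None,
) -> PdfGrid:
    """Joint Gaussian-product KDE conditioned on the trailing variates.

    ``data`` is ``(n, d)`` with the first ``k = len(output_axes)``
    columns the outputs and the remaining ``d - k`` the conditioning
    variables; Silverman bandwidths are computed on the full ``d``
    dimensions.  The joint density is evaluated at the conditioning
    point over the output grid and renormalized there, which equals
    conditioning up to the dropped constant.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an (n, d) matrix")
    k = len(output_axes)
    cond_values = np.asarray(cond_values, dtype=float)
    if data.shape[1] != k + cond_values.size:
        raise ValueError(
            f"data has {data.shape[1]} columns; expected "
            f"{k} outputs + {cond_values.size} conditioning variables"
        )
    bw = silverman_bandwidths(data)
    # kernel weight of each observation at the conditioning point
    if cond_values.size:
        z = (cond_values[None, :] - data[:, k:]) / bw.h[k:][None, :]
        logw = -0.5 * np.sum(z * z, axis=1)
        logw -= logw.max()  # guard against underflow far from every row
        w = np.exp(logw)
    else:
        w = np.ones(data.shape[0])
    # product kernel over the output dimensions, one matrix per axis
    mats = []
    for dim in range(k):
        g = np.asarray(output_axes[dim], dtype=float)[:, None]
        z = (g - data[None, :, dim]) / bw.h[dim]
        mats.append(np.exp(-0.5 * z * z))
    if k == 1:
        vals = mats[0] @ w
    elif k == 2:
        vals = (mats[0] * w[None, :]) @ mats[1].T
    else:  # pragma: no cover - outputs beyond 2-D unused in practice
        vals = np.einsum("i...,i->...", np.stack(
            [np.multiply.reduce([m[:, i] for m in mats], axis=0) for i in range(data.shape[0])]
        ), w)
    pdf = PdfGrid(tuple(output_axes), vals, axis_names=axis_names)
    if pdf.total_mass() <= 0:
        raise ValueError("KDE mass underflowed to zero on the output grid")
    return pdf.normalize()


def kde_conditioned_pdf(
    ensemble: pd.DataFrame,
    patient_unmodelables: tuple[float, float],
    output_axes: tuple[np.ndarray, np.ndarray],
) -> PdfGrid:
    """Data-derived pdf over (IW, TS) for one patient.

    ``ensemble`` must carry columns ``IW, TS, n_bar, v_bar`` (one row per
    ensemble patient at that patient's diagnosis time); the 4-D joint KDE
    is conditioned on the patient's ``(n_bar, v_bar)``.
    """
    cols = ["IW", "TS", "n_bar", "v_bar"]
    missing = [c for c in cols if c not in ensemble.columns]
    if missing:
        raise ValueError(f"ensemble is missing columns {missing}")
    data = ensemble[cols].to_numpy(dtype=float)
    return gaussian_kde_conditional(
        data, patient_unmodelables, output_axes, axis_names=("IW", "TS")
    )


# ---------------------------------------------------------------------------
# fusion and pdf summaries
# ---------------------------------------------------------------------------

def fuse_pdfs(model_pdf: PdfGrid, data_pdf: PdfGrid) -> PdfGrid:
    """Cell-wise product of the two densities, renormalized.

    Symmetric in its arguments.  Disjoint supports raise
    :class:`IncompatibleEvidenceError` rather than silently flooring.
    """
    if not model_pdf.same_axes(data_pdf):
        raise ValueError("cannot fuse densities defined on different axes")
    product = model_pdf.values * data_pdf.values
    total = product.sum() * model_pdf.cell_volume
    if total <= 0:
        raise IncompatibleEvidenceError(
            "model and data densities have disjoint supports; "
            "their product carries no information"
        )
    return PdfGrid(
        model_pdf.axes,
        product / total,
        normalized=True,
        axis_names=model_pdf.axis_names or data_pdf.axis_names,
    )


def _require_normalized(pdf: PdfGrid, what: str) -> None:
    if not pdf.normalized:
        raise ValueError(f"{what} requires a normalized density")


def pdf_expected_value(pdf: PdfGrid) -> np.ndarray:
    """Per-axis mean of the discretized density."""
    _require_normalized(pdf, "expected value")
    vol = pdf.cell_volume
    means = []
    for i, axis in enumerate(pdf.axes):
        other = tuple(j for j in range(pdf.ndim) if j != i)
        marg = pdf.values.sum(axis=other) if other else pdf.values
        means.append(float((axis * marg).sum() * vol))
    return np.array(means)


def pdf_modes(pdf: PdfGrid, rel_tol: float = 0.05) -> np.ndarray:
    """All local maxima within ``rel_tol`` (relative) of the global
    maximum, sorted by decreasing density; shape ``(n_modes, ndim)``."""
    _require_normalized(pdf, "mode extraction")
    vals = pdf.values
    if np.isclose(vals.max(), vals.min()):
        raise ValueError("flat density: no isolated mode")
    local_max = vals == ndimage.maximum_filter(vals, size=3, mode="nearest")
    keep = local_max & (vals >= (1.0 - rel_tol) * vals.max())
    # a flat plateau passes the filter everywhere on the plateau; keep all
    idx = np.argwhere(keep)
    order = np.argsort(-vals[tuple(idx.T)], kind="stable")
    idx = idx[order]
    coords = np.stack(
        [pdf.axes[dim][idx[:, dim]] for dim in range(pdf.ndim)], axis=1
    )
    return coords


def effective_variance(pdf: PdfGrid, on_degenerate: str = "raise") -> float:
    """Log-determinant of the central second-moment matrix of a 2-D pdf.

    A scalar spread measure: smaller means a sharper prediction.  A
    non-positive determinant (all mass in one cell, or perfectly
    correlated axes) either raises (default) or returns ``-inf`` when
    ``on_degenerate='value'``.
    """
    _require_normalized(pdf, "effective variance")
    if pdf.ndim != 2:
        raise ValueError("effective variance is defined for 2-D densities")
    mu = pdf_expected_value(pdf)
    y1 = pdf.axes[0][:, None] - mu[0]
    y2 = pdf.axes[1][None, :] - mu[1]
    vol = pdf.cell_volume
    s11 = float((y1 * y1 * pdf.values).sum() * vol)
    s22 = float((y2 * y2 * pdf.values).sum() * vol)
    s12 = float((y1 * y2 * pdf.values).sum() * vol)
    det = s11 * s22 - s12 * s12
    if det <= 0:
        if on_degenerate == "value":
            return float("-inf")
        raise ValueError(
            f"degenerate second-moment matrix (det = {det:g}); "
            "the density is concentrated in a single cell or line"
        )
    return float(np.log(det))


def histogram_pdf(
    samples: np.ndarray, axis: np.ndarray, axis_name: str | None = None
) -> PdfGrid:
    """Normalized 1-D density from samples binned onto a uniform axis.

    Bin edges sit midway between axis points; samples outside the axis
    fall into the end bins.  Used to place a sweep-outcome histogram on
    the shared output grid required by the fusion rule.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError("no finite samples to histogram")
    axis = np.asarray(axis, dtype=float)
    if axis.size == 1:
        vals = np.array([float(samples.size)])
    else:
        edges = np.concatenate(
            ([-np.inf], (axis[:-1] + axis[1:]) / 2.0, [np.inf])
        )
        vals = np.histogram(samples, bins=edges)[0].astype(float)
    names = (axis_name,) if axis_name else None
    return PdfGrid((axis,), vals, axis_names=names).normalize()


def pdf_entropy(pdf: PdfGrid) -> float:
    """Differential Shannon entropy of the discretized density (nats)."""
    _require_normalized(pdf, "entropy")
    p = pdf.values[pdf.values > 0]
    return float(-(p * np.log(p)).sum() * pdf.cell_volume)


def build_output_grid(
    *point_sets: np.ndarray,
    n_points: int = 100,
    pad_fraction: float = 0.10,
    axis_names: tuple[str, ...] = ("IW", "TS"),
) -> tuple[np.ndarray, ...]:
    """Shared output-space axes spanning the union of the given point
    sets (each ``(m_i, ndim)``), padded by ``pad_fraction`` of the range
    per side."""
    pts = np.vstack([np.asarray(p, dtype=float).reshape(-1, len(axis_names))
                     for p in point_sets])
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if pts.size == 0:
        raise ValueError("no finite points to span an output grid")
    axes = []
    for dim in range(pts.shape[1]):
        lo, hi = float(pts[:, dim].min()), float(pts[:, dim].max())
        span = hi - lo
        if span <= 0:
            span = max(abs(hi), 1.0)
        lo -= pad_fraction * span
        hi += pad_fraction * span
        axes.append(np.linspace(lo, hi, n_points))
    return tuple(axes)
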