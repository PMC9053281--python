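"""Prediction-quality scores.

For each patient the relative error of a predictor ``k`` against the
ground truth ``y^r`` over the ``N_y = 2`` clinical outputs is

    d_k = sqrt( (1/N_y) * sum_i (1 - <y_i^k> / y_i^r)^2 )

and the partial (per-output) errors are the absolute relative
deviations.  Two predictors (mechanistic model alone, fused posterior)
are compared with a tolerance ``eps``: within ``eps * d_m`` of each
other the prediction is *unchanged*, below it *improved*, above it
*deteriorated*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pdfgrid import PdfGrid

__all__ = [
    "IMPROVED",
    "UNCHANGED",
    "DETERIORATED",
    "ScoreSummary",
    "relative_error",
    "partial_errors",
    "classify",
    "score_summary",
    "marginal_overlap",
    "mse",
]

IMPROVED = "improved"
UNCHANGED = "unchanged"
DETERIORATED = "deteriorated"


def _as_pair(outputs) -> np.ndarray:
    if hasattr(outputs, "as_array"):
        return outputs.as_array()
    arr = np.asarray(outputs, dtype=float)
    if arr.shape != (2,):
        raise ValueError(f"expected two clinical outputs, got shape {arr.shape}")
    return arr


def relative_error(expected, truth) -> float:
    """Root-mean-square relative error over the two outputs."""
    e, r = _as_pair(expected), _as_pair(truth)
    if np.any(r == 0):
        raise ValueError("relative error undefined: a truth component is zero")
    dev = 1.0 - e / r
    return float(np.sqrt(np.mean(dev * dev)))


def partial_errors(expected, truth) -> tuple[float, float]:
    """Absolute relative deviation per output, ``(dIW, dTS)``."""
    e, r = _as_pair(expected), _as_pair(truth)
    if np.any(r == 0):
        raise ValueError("partial error undefined: a truth component is zero")
    dev = np.abs(1.0 - e / r)
    return float(dev[0]), float(dev[1])


def classify(d_m: float, d_b: float, eps: float = 0.05) -> str:
    """Compare the fused error ``d_b`` to the model-only error ``d_m``.

    Boundary equalities resolve to *unchanged*.
    """
    if d_m < 0 or d_b < 0:
        raise ValueError("errors must be non-negative")
    if abs(d_b - d_m) <= eps * d_m:
        return UNCHANGED
    if d_b > (1.0 + eps) * d_m:
        return DETERIORATED
    return IMPROVED


@dataclass(frozen=True)
class ScoreSummary:
    """Improved / unchanged / deteriorated ratios, pooled and per
    replicate (mean +/- sd across replicates)."""

    S_i: float
    S_u: float
    S_d: float
    per_replicate: pd.DataFrame
    S_i_sd: float
    S_u_sd: float
    S_d_sd: float


def score_summary(
    classifications: Sequence[str],
    replicate_ids: Sequence | None = None,
) -> ScoreSummary:
    """Ratios of improved/unchanged/deteriorated cases.

    With ``replicate_ids`` the ratios are computed per replicate and the
    summary reports their mean and standard deviation (ddof=1 when more
    than one replicate); without, the pooled ratios are returned with
    zero spread.
    """
    labels = list(classifications)
    if not labels:
        raise ValueError("no records to summarize")
    if replicate_ids is None:
        replicate_ids = [0] * len(labels)
    df = pd.DataFrame({"label": labels, "replicate": list(replicate_ids)})
    per = (
        df.groupby("replicate")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=[IMPROVED, UNCHANGED, DETERIORATED], fill_value=0.0)
    )
    means = per.mean(axis=0)
    sds = per.std(axis=0, ddof=1) if len(per) > 1 else per.iloc[0] * 0.0
    return ScoreSummary(
        S_i=float(means[IMPROVED]),
        S_u=float(means[UNCHANGED]),
        S_d=float(means[DETERIORATED]),
        per_replicate=per,
        S_i_sd=float(sds[IMPROVED]),
        S_u_sd=float(sds[UNCHANGED]),
        S_d_sd=float(sds[DETERIORATED]),
    )


def marginal_overlap(pdf_a: PdfGrid, pdf_b: PdfGrid, axis: int) -> float:
    """Overlap of the two marginal densities on one axis.

    Both pdfs are marginalized onto the axis (after normalization) and
    the overlap is the Riemann integral of the pointwise minimum: 1 for
    identical marginals, 0 for disjoint supports.
    """
    if pdf_a.ndim != pdf_b.ndim or not np.array_equal(
        pdf_a.axes[axis], pdf_b.axes[axis]
    ):
        raise ValueError("marginal overlap requires a shared axis")
    ma = pdf_a.normalize().marginal(axis)
    mb = pdf_b.normalize().marginal(axis)
    return float(np.minimum(ma.values, mb.values).sum() * ma.cell_volume)


def mse(predicted: Iterable[float], observed: Iterable[float]) -> float:
    """Mean squared error between two equal-length sequences."""
    p = np.asarray(list(predicted), dtype=float)
    o = np.asarray(list(observed), dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be nonempty and equal-length")
    return float(np.mean((p - o) ** 2))
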