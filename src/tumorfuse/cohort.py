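"""Virtual-patient cohorts and the patient-ensemble table.

A cohort is generated by drawing five full-model parameters (``D``,
``b``, ``h1``, ``g1``, ``g2``) i.i.d. uniform over configured ranges;
every patient starts from the same initial condition and is integrated
for a fixed horizon (3 years by default) with all variables recorded
monthly.  The ensemble table then reads, for each patient, the clinical
outputs and unmodelable summaries at a per-patient diagnosis time drawn
uniformly on integer months in ``[t0 - 6, t0 + 6]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glioma import (
    FrontError,
    FullModelParams,
    IntegrationError,
    infiltration_width,
    simulate_full_model_batch,
    tumor_size,
)
from .grids import Grid1D

__all__ = [
    "VirtualPatient",
    "CohortRun",
    "DEFAULT_SAMPLING_RANGES",
    "sample_cohort",
    "run_cohort",
    "build_ensemble",
]

logger = logging.getLogger(__name__)

#: Uniform sampling ranges for the five varied parameters (per month /
#: mm² per month).  Package reference choices; see docs/methods.md.
DEFAULT_SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "D": (0.3, 3.0),
    "b": (0.3, 3.0),
    "h1": (5.0, 20.0),
    "g1": (0.15, 0.6),
    "g2": (0.05, 0.3),
}

_VARIABLE_NAMES = ("D", "b", "h1", "g1", "g2")


@dataclass(frozen=True)
class VirtualPatient:
    """One virtual patient: an id and a sampled full-model parameter set."""

    patient_id: int
    params: FullModelParams


@dataclass
class CohortRun:
    """Monthly trajectories of a simulated cohort.

    ``outputs`` has shape ``(N, n_months, 4)`` with the last axis
    ``(IW, TS, n_bar, v_bar)``; ``c_profiles`` has shape
    ``(N, n_months, nx)``.  ``months`` runs 0, 1, ..., horizon.
    """

    patients: list[VirtualPatient]
    grid: Grid1D
    months: np.ndarray
    outputs: np.ndarray
    c_profiles: np.ndarray
    failed_ids: list[int] = field(default_factory=list)

    OUTPUT_COLUMNS = ("IW", "TS", "n_bar", "v_bar")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def month_index(self, month: float) -> int:
        idx = np.nonzero(np.isclose(self.months, month))[0]
        if idx.size == 0:
            raise ValueError(f"month {month} not in the stored series")
        return int(idx[0])

    def outputs_at(self, month: float) -> pd.DataFrame:
        """Table of (IW, TS, n_bar, v_bar) across patients at one month."""
        k = self.month_index(month)
        df = pd.DataFrame(self.outputs[:, k, :], columns=self.OUTPUT_COLUMNS)
        df.insert(0, "patient_id", [p.patient_id for p in self.patients])
        return df

    def c_profile(self, patient_index: int, month: float) -> np.ndarray:
        return self.c_profiles[patient_index, self.month_index(month)]

    def truth(self, patient_index: int, month: float) -> np.ndarray:
        """Ground-truth (IW, TS) of one patient at one month."""
        return self.outputs[patient_index, self.month_index(month), :2]

    def parameter_table(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p.patient_id, **{k: getattr(p.params, k) for k in _VARIABLE_NAMES}}
            for p in self.patients
        ]
        return pd.DataFrame(rows)

    def save_manifest(self, path: str | Path, seed: int | None = None) -> None:
        """JSON manifest: grid, months and per-patient parameters."""
        manifest = {
            "seed": seed,
            "grid": {"length": self.grid.length, "n_nodes": self.grid.n_nodes},
            "months": self.months.tolist(),
            "failed_ids": self.failed_ids,
            "patients": self.parameter_table().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(manifest, indent=1))


def sample_cohort(
    N: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    base_params: FullModelParams | None = None,
    seed: int | None = None,
) -> list[VirtualPatient]:
    """Draw ``N`` virtual patients with i.i.d. uniform parameters.

    ``ranges`` maps a subset of {D, b, h1, g1, g2} to ``(low, high)``
    bounds (``low == high`` pins the value); unlisted parameters stay at
    their ``base_params`` values.  Fully reproducible under ``seed``.
    """
    if N < 1:
        raise ValueError(f"cohort size must be >= 1, got {N}")
    ranges = DEFAULT_SAMPLING_RANGES if ranges is None else ranges
    unknown = set(ranges) - set(_VARIABLE_NAMES)
    if unknown:
        raise ValueError(f"cannot vary parameters {sorted(unknown)}")
    for name, (low, high) in ranges.items():
        if high < low:
            raise ValueError(f"range for {name} has high < low")
    base = base_params or FullModelParams()
    rng = np.random.default_rng(seed)
    draws = {}
    for name, (low, high) in ranges.items():
        draws[name] = (
            np.full(N, low) if high == low else rng.uniform(low, high, size=N)
        )
    patients = []
    for i in range(N):
        overrides = {name: float(draws[name][i]) for name in ranges}
        params = FullModelParams(**{**base.__dict__, **overrides})
        patients.append(VirtualPatient(patient_id=i, params=params))
    return patients


def _extract_outputs(c: np.ndarray, n: np.ndarray, v: np.ndarray, grid: Grid1D) -> np.ndarray:
    """(IW, TS, n_bar, v_bar) for one saved state; NaN IW if no front."""
    try:
        iw = infiltration_width(c, grid)
    except FrontError:
        iw = np.nan
    return np.array(
        [iw, tumor_size(c, grid), np.trapezoid(n, grid.x), np.trapezoid(v, grid.x)]
    )


def run_cohort(
    patients: list[VirtualPatient],
    grid: Grid1D,
    horizon: float = 36.0,
    save_every: float = 1.0,
) -> CohortRun:
    """Integrate the full model for every patient and record monthly
    outputs and density profiles.

    All patients share the base initial condition; only the five sampled
    parameters differ, so the whole cohort integrates as one array.  If
    the batched run diverges, patients are re-run one by one and the
    failing ids are excluded (and logged), never silently dropped.
    """
    if not patients:
        raise ValueError("empty cohort")
    base = patients[0].params
    varied = {
        name: np.array([getattr(p.params, name) for p in patients])
        for name in _VARIABLE_NAMES
    }
    months = np.arange(0.0, horizon + 0.5 * save_every, save_every)
    initial = base.initial_state(grid)

    keep = list(range(len(patients)))
    failed: list[int] = []
    try:
        states = simulate_full_model_batch(
            initial, base, grid, varied, months[1:]
        )
    except IntegrationError:
        # isolate the failing patients
        ok_states = []
        keep = []
        for i, p in enumerate(patients):
            try:
                one = simulate_full_model_batch(
                    initial, base, grid,
                    {k: np.array([varied[k][i]]) for k in varied}, months[1:],
                )
                ok_states.append(one)
                keep.append(i)
            except IntegrationError:
                failed.append(p.patient_id)
                logger.warning("patient %d failed to integrate; excluded", p.patient_id)
        if not keep:
            raise IntegrationError("every patient in the cohort failed to integrate")
        states = {
            k: np.concatenate([s[k] for s in ok_states], axis=1) for k in ("c", "n", "v")
        }
    kept_patients = [patients[i] for i in keep]
    N = len(kept_patients)
    n_months = months.size
    outputs = np.empty((N, n_months, 4))
    c_profiles = np.empty((N, n_months, grid.n_nodes))
    for i in range(N):
        outputs[i, 0] = _extract_outputs(initial.c, initial.n, initial.v, grid)
        c_profiles[i, 0] = initial.c
    for k in range(1, n_months):
        for i in range(N):
            c, n, v = states["c"][k - 1, i], states["n"][k - 1, i], states["v"][k - 1, i]
            outputs[i, k] = _extract_outputs(c, n, v, grid)
            c_profiles[i, k] = c
    if failed:
        logger.warning("%d of %d patients excluded", len(failed), len(patients))
    return CohortRun(
        patients=kept_patients,
        grid=grid,
        months=months,
        outputs=outputs,
        c_profiles=c_profiles,
        failed_ids=failed,
    )


def build_ensemble(
    cohort: CohortRun,
    t0: float,
    seed: int | None = None,
    half_width: int = 6,
) -> pd.DataFrame:
    """Patient-ensemble table at diagnosis times around ``t0``.

    Each patient's diagnosis time ``t_d`` is drawn uniformly on the
    integer months in ``[t0 - half_width, t0 + half_width]`` (clamped to
    >= 1 month) and the row ``(IW, TS, n_bar, v_bar)`` is read from the
    stored monthly series at ``t_d``.
    """
    rng = np.random.default_rng(seed)
    lo = max(1, int(round(t0)) - half_width)
    hi = int(round(t0)) + half_width
    if hi > cohort.months.max() + 1e-9:
        raise ValueError(
            f"diagnosis window extends to {hi} months but the stored horizon "
            f"is {cohort.months.max():g} months"
        )
    td = rng.integers(lo, hi + 1, size=cohort.n_patients)
    rows = []
    for i, patient in enumerate(cohort.patients):
        k = cohort.month_index(float(td[i]))
        iw, ts, n_bar, v_bar = cohort.outputs[i, k]
        rows.append(
            {
                "patient_id": patient.patient_id,
                "IW": iw,
                "TS": ts,
                "n_bar": n_bar,
                "v_bar": v_bar,
                "t_d": int(td[i]),
            }
        )
    table = pd.DataFrame(rows)
    if not np.all(np.isfinite(table[["IW", "TS", "n_bar", "v_bar"]].to_numpy())):
        raise ValueError("ensemble contains non-finite rows (undefined fronts?)")
    return table
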