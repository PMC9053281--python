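"""End-to-end synthetic glioma benchmark.

Protocol: generate a virtual cohort from the full model, build the
patient ensemble at randomized diagnosis times, and for every patient
and every (clinical presentation time t0, prediction time tp) pair

1. run the Fisher-Kolmogorov parameter sweep from the patient's density
   profile at t0 and build the tolerance-box model pdf at t0 + tp;
2. build the data pdf by conditioning the ensemble KDE on the patient's
   unmodelables (n_bar, v_bar) at t0;
3. fuse the two pdfs, take expected values, and score both predictors
   against the full-model ground truth at t0 + tp.

Replicates rerun the whole pipeline with independent streams spawned
from one root seed, so a run is fully determined by (config, seed).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fusion, scoring
from .cohort import (
    DEFAULT_SAMPLING_RANGES,
    CohortRun,
    build_ensemble,
    run_cohort,
    sample_cohort,
)
from .glioma import FullModelParams
from .grids import Grid1D
from .pdfgrid import PdfGrid

__all__ = ["ExperimentConfig", "run_benchmark", "overlap_report", "failure_map"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything that determines a benchmark run (with the seed)."""

    n_patients: int = 50
    replicates: int = 10
    t0_list: tuple[float, ...] = (24.0,)
    tp_list: tuple[float, ...] = (6.0, 9.0, 12.0)
    horizon: float = 36.0
    grid_length: float = 400.0
    grid_nodes: int = 401
    sampling_ranges: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLING_RANGES))
    sweep_resolution: int = 20
    tolerance_alpha: float = 0.05
    classification_eps: float = 0.05
    output_grid_points: int = 100
    output_grid_pad: float = 0.10
    td_half_width: int = 6
    leave_one_out: bool = False
    force_uniform_data: bool = False
    force_uniform_model: bool = False
    seed: int = 0
    base_params: FullModelParams = field(default_factory=FullModelParams)

    def __post_init__(self) -> None:
        needed = max(self.t0_list) + max(self.tp_list)
        if needed > self.horizon:
            raise ValueError(
                f"horizon {self.horizon} too short for t0+tp = {needed} months"
            )

    @property
    def grid(self) -> Grid1D:
        return Grid1D(self.grid_length, self.grid_nodes)

    @property
    def sweep_ranges(self) -> dict[str, tuple[float, float]]:
        return {"D": tuple(self.sampling_ranges["D"]), "b": tuple(self.sampling_ranges["b"])}


def _uniform_like(pdf: PdfGrid) -> PdfGrid:
    vals = np.full_like(pdf.values, 1.0)
    return PdfGrid(pdf.axes, vals, axis_names=pdf.axis_names).normalize()


def _patient_records(
    config: ExperimentConfig,
    cohort: CohortRun,
    ensembles: dict[float, pd.DataFrame],
    replicate: int,
) -> list[dict]:
    grid = config.grid
    records: list[dict] = []
    for t0 in config.t0_list:
        ensemble = ensembles[t0]
        ens_pts = ensemble[["IW", "TS"]].to_numpy()
        unmods_t0 = cohort.outputs_at(t0)
        for i, patient in enumerate(cohort.patients):
            c_t0 = cohort.c_profile(i, t0)
            try:
                outcomes = fusion.fk_sweep_outcomes(
                    c_t0, config.sweep_ranges, config.sweep_resolution,
                    grid, list(config.tp_list),
                )
            except Exception:  # noqa: BLE001 - per-patient failures logged
                logger.exception("FK sweep failed for patient %d", patient.patient_id)
                continue
            n_bar, v_bar = unmods_t0.loc[
                unmods_t0.patient_id == patient.patient_id, ["n_bar", "v_bar"]
            ].iloc[0]
            for k, tp in enumerate(config.tp_list):
                try:
                    truth = cohort.truth(i, t0 + tp)
                    axes = fusion.build_output_grid(
                        outcomes[k], ens_pts,
                        n_points=config.output_grid_points,
                        pad_fraction=config.output_grid_pad,
                    )
                    model_pdf = fusion.tolerance_box_pdf(
                        outcomes[k], axes, config.tolerance_alpha
                    )
                    ens = ensemble
                    if config.leave_one_out:
                        ens = ensemble[ensemble.patient_id != patient.patient_id]
                    data_pdf = fusion.kde_conditioned_pdf(ens, (n_bar, v_bar), axes)
                    if config.force_uniform_model:
                        model_pdf = _uniform_like(model_pdf)
                    if config.force_uniform_data:
                        data_pdf = _uniform_like(data_pdf)
                    fused = fusion.fuse_pdfs(model_pdf, data_pdf)
                    ev_m = fusion.pdf_expected_value(model_pdf)
                    ev_b = fusion.pdf_expected_value(fused)
                    d_m = scoring.relative_error(ev_m, truth)
                    d_b = scoring.relative_error(ev_b, truth)
                    diw_m, dts_m = scoring.partial_errors(ev_m, truth)
                    diw_b, dts_b = scoring.partial_errors(ev_b, truth)
                    s_m = fusion.effective_variance(model_pdf, on_degenerate="value")
                    s_b = fusion.effective_variance(fused, on_degenerate="value")
                    records.append(
                        {
                            "replicate": replicate,
                            "patient_id": patient.patient_id,
                            "t0": t0,
                            "tp": tp,
                            "IW_r": truth[0],
                            "TS_r": truth[1],
                            "IW_m": ev_m[0],
                            "TS_m": ev_m[1],
                            "IW_b": ev_b[0],
                            "TS_b": ev_b[1],
                            "d_m": d_m,
                            "d_b": d_b,
                            "dIW_m": diw_m,
                            "dIW_b": diw_b,
                            "dTS_m": dts_m,
                            "dTS_b": dts_b,
                            "s_m": s_m,
                            "s_b": s_b,
                            "classification": scoring.classify(
                                d_m, d_b, config.classification_eps
                            ),
                        }
                    )
                except Exception:  # noqa: BLE001
                    logger.exception(
                        "scoring failed for patient %d at t0=%g tp=%g",
                        patient.patient_id, t0, tp,
                    )
    return records


def run_benchmark(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full benchmark; returns (records, summary).

    ``records`` has one row per (replicate, patient, t0, tp) with both
    predictors' expected values, errors, effective variances and the
    improvement classification.  ``summary`` aggregates the improved /
    unchanged / deteriorated ratios per (t0, tp): mean and sd across
    replicates.
    """
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(config.replicates)
    all_records: list[dict] = []
    for rep, ss in enumerate(rep_seeds):
        t_start = time.perf_counter()
        cohort_seed, ensemble_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        patients = sample_cohort(
            config.n_patients, config.sampling_ranges, config.base_params, cohort_seed
        )
        cohort = run_cohort(patients, config.grid, config.horizon)
        ensembles = {
            t0: build_ensemble(cohort, t0, ensemble_seed + int(t0), config.td_half_width)
            for t0 in config.t0_list
        }
        all_records.extend(_patient_records(config, cohort, ensembles, rep))
        logger.info(
            "replicate %d/%d done in %.1f s",
            rep + 1, config.replicates, time.perf_counter() - t_start,
        )
    records = pd.DataFrame(all_records)
    if records.empty:
        raise RuntimeError("benchmark produced no records")
    rows = []
    for (t0, tp), grp in records.groupby(["t0", "tp"]):
        summ = scoring.score_summary(grp["classification"], grp["replicate"])
        rows.append(
            {
                "t0": t0,
                "tp": tp,
                "S_i": summ.S_i,
                "S_u": summ.S_u,
                "S_d": summ.S_d,
                "S_i_sd": summ.S_i_sd,
                "S_u_sd": summ.S_u_sd,
                "S_d_sd": summ.S_d_sd,
                "n_records": len(grp),
            }
        )
    return records, pd.DataFrame(rows)


def overlap_report(
    config: ExperimentConfig,
    cohort: CohortRun,
    t0_pairs: tuple[tuple[float, float], ...] = ((12.0, 18.0), (24.0, 30.0)),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient overlap of the data-pdf marginals at two successive
    presentation times.

    High overlap means the unmodelable-conditioned density has reached a
    steady state between the two times; low overlap marks transient
    regimes where the data correction points at outdated outputs.
    """
    rows = []
    for t0_a, t0_b in t0_pairs:
        ens_a = build_ensemble(cohort, t0_a, seed + int(t0_a), config.td_half_width)
        ens_b = build_ensemble(cohort, t0_b, seed + int(t0_b), config.td_half_width)
        axes = fusion.build_output_grid(
            ens_a[["IW", "TS"]].to_numpy(),
            ens_b[["IW", "TS"]].to_numpy(),
            n_points=config.output_grid_points,
            pad_fraction=config.output_grid_pad,
        )
        out_a = cohort.outputs_at(t0_a)
        out_b = cohort.outputs_at(t0_b)
        for i, patient in enumerate(cohort.patients):
            ua = out_a.loc[out_a.patient_id == patient.patient_id, ["n_bar", "v_bar"]].iloc[0]
            ub = out_b.loc[out_b.patient_id == patient.patient_id, ["n_bar", "v_bar"]].iloc[0]
            pdf_a = fusion.kde_conditioned_pdf(ens_a, tuple(ua), axes)
            pdf_b = fusion.kde_conditioned_pdf(ens_b, tuple(ub), axes)
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "t0_a": t0_a,
                    "t0_b": t0_b,
                    "overlap_IW": scoring.marginal_overlap(pdf_a, pdf_b, 0),
                    "overlap_TS": scoring.marginal_overlap(pdf_a, pdf_b, 1),
                    "IW_r": cohort.truth(i, t0_b)[0],
                    "TS_r": cohort.truth(i, t0_b)[1],
                }
            )
    return pd.DataFrame(rows)


def failure_map(records: pd.DataFrame, cohort: CohortRun) -> pd.DataFrame:
    """Classification of each record joined to the patient's sampled
    (D, b) coordinates, ready for a parameter-space scatter of the
    deteriorated ('failure') cases."""
    params = cohort.parameter_table()
    merged = records.merge(params, on="patient_id", how="left")
    merged["failed"] = merged["classification"] == scoring.DETERIORATED
    return merged[
        ["patient_id", "t0", "tp", "D", "b", "h1", "g1", "g2", "classification", "failed"]
    ]
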