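# tumorfuse

Personalized tumor-growth prediction by Bayesian fusion of a mechanistic
model prior with a kernel-density estimate over a patient ensemble.

## The problem

Clinical prediction of tumor dynamics faces two chronic obstacles: most
measured patient variables have no mechanistic equation (so mechanistic
models ignore them), and each patient is observed at very few
time-points (so statistical learning alone cannot infer their
dynamics).  `tumorfuse` implements a fusion rule that addresses both at
once.  Write **Y** for the clinical outputs, **x**<sub>m</sub> for the
*modelable* patient state (a quantity a mechanistic model evolves, e.g.
a tumor-density profile) and **x**<sub>u</sub> for the *unmodelable*
variables (measured but not mechanistically described, e.g. tissue
oxygenation, patient age, marker expression).  Then

p(**Y** | **x**<sub>m</sub>, **x**<sub>u</sub>) ∝
p(**Y** | **x**<sub>m</sub>) · p(**Y** | **x**<sub>u</sub>)

The first factor is a *model-derived* density: a mechanistic model run
from the patient's state over a swept parameter box, turned into a
density over outputs with a ±5% relative tolerance box.  The second is
a *data-derived* density: a Gaussian-product kernel density estimate
(Silverman rule-of-thumb bandwidths, h<sub>i</sub> = σ<sub>i</sub>
[4/((d+2)n)]<sup>1/(d+4)</sup>) over an N-patient ensemble, evaluated
at the patient's unmodelables and renormalized over the outputs.  Their
cell-wise product, renormalized on a shared output grid, is the fused
posterior used for prediction (expected value or mode).

Three disease settings are built in:

* **Glioma (synthetic benchmark)** — a full hypoxia-plasticity PDE
  system (tumor density, oxygen, vasculature, with a motility /
  proliferation switch, angiogenesis and vaso-occlusion) generates
  virtual patients; the Fisher-Kolmogorov equation
  ∂c/∂t = D ∂²c/∂x² + b c(1−c) is the deliberately simplified prior.
  Outputs: infiltration width (IW, distance between the 80% and 2%
  of-maximum front points) and tumor size (TS, profile integral divided
  by its maximum).  Unmodelables: tissue integrals of oxygen and
  vasculature.
* **B-CLL kinetics** — the two-compartment deuterated-water labeling
  solution predicts the labeled-cell fraction at day 50 (f₅₀);
  unmodelables are CD38 expression, age, white-blood-cell growth rate
  and V_H mutation status (synthetic table generator emulating the
  17-patient cohort structure).
* **Ovarian relapse** — sensitive/resistant subpopulations under a
  NACT → surgery → adjuvant-chemotherapy schedule, integrated in closed
  form; the output is time-to-relapse (TtR), the unmodelable is age at
  diagnosis, and the chemotherapy kill rate is fitted per patient from
  the first-cycle volume change.

A full scoring suite quantifies what the fusion does: relative errors
d = √(½[(1−⟨IW⟩/IWʳ)² + (1−⟨TS⟩/TSʳ)²]), per-output partial errors,
an ε = 0.05 improved/unchanged/deteriorated classification, effective
variance s = ln det Σ of a 2-D density, marginal-overlap diagnostics
and MSE.

## Worked example

`examples/cohort_benchmark.py` scores the fusion on two replicate
virtual cohorts of 25 glioma patients at late clinical presentation
(t0 = 24 months):

```
  t0   tp  S_i  S_u  S_d   S_i_sd
24.0  6.0 0.96  0.0 0.04 0.056569
24.0  9.0 0.96  0.0 0.04 0.056569
24.0 12.0 0.96  0.0 0.04 0.056569

median relative errors (model alone vs fused):
           d_m       d_b
tp
6.0   0.368803  0.271613
9.0   0.385630  0.278761
12.0  0.395769  0.284853
```

`S_i` is the fraction of patients whose prediction the fusion improved
(here 96% at every horizon); the median relative error drops from
≈0.37–0.40 (mechanistic prior alone) to ≈0.27–0.28 after fusion, and
the gap widens with the prediction horizon.  The other examples
(`glioma_patient_fusion.py`, `cll_unmodelables.py`,
`ovarian_relapse.py`) each build one small input, run one capability
and print what it computes.

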