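# Methods

This note documents the models, estimators, numerical choices and
study-design decisions behind `tumorfuse`, in the spirit of a model
documentation page: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## 1. The fusion rule

The package predicts a patient's clinical outputs **Y** by multiplying
two densities on a shared discretized output grid:

* the **model-derived density** p(**Y** | **x**_m), obtained by running
  a mechanistic model from the patient's modelable state over a swept
  parameter box and converting the finite set of outcomes into a
  density, and
* the **data-derived density** p(**Y** | **x**_u), a Gaussian-product
  KDE over an ensemble of patients, evaluated at the patient's
  unmodelable variables and renormalized over the outputs.

The product is renormalized cell-wise (Riemann convention: values ×
cell volume sum to 1).  The rule treats the mechanistic prediction as
an informative Bayesian prior that the patient-specific statistical
evidence reweights.  Two exact reductions follow and are tested: a
uniform data density returns the model density unchanged, and a uniform
model density reduces the method to nonparametric (kernel) regression.

Disjoint supports raise an explicit "incompatible evidence" error
rather than silently flooring the density: a zero product carries no
information and flooring would fabricate some.

**Output grid.** Both densities need common axes.  The default grid is
100 × 100 per output pair, spanning the union of the sweep outcomes and
the ensemble rows, padded by 10% of the range per side.  Grid extent
and resolution are the main sensitivity knobs of the whole pipeline;
both are configurable, and the tests check that the scoring conclusions
are stable under the defaults.

**Density summaries.** Expected value (per-axis mean), modes (local
maxima within a relative tolerance of the global maximum), and the
effective variance s = ln det Σ with Σ the central second-moment matrix
computed by quadrature; s is a scalar spread measure (smaller = sharper
prediction).  A single-cell density has a singular Σ; that degenerate
case raises by default or returns −∞ under `on_degenerate="value"`.

**Tolerance box.** The density assigned to an output-grid point y* is
proportional to the number of sweep outcomes y satisfying
(1−α) y* < y < (1+α) y* componentwise, with α = 0.05; final
renormalization over the grid reproduces the normalization by the total
covered area.  This counting estimator is checked against a brute-force
double loop.

**Bandwidths.** Silverman's rule of thumb per dimension,
h_i = σ_i [4/((d+2) n)]^{1/(d+4)}, with σ_i the sample standard
deviation over the ensemble, d the joint dimension (outputs +
conditioning variables) and n the ensemble size.  Columns with zero
variance make the rule degenerate and raise with the column named.

## 2. Glioma models

The *full model* couples tumor density c(x,t), oxygen n(x,t) and
functional vasculature v(x,t) on 0 ≤ x ≤ L (all normalized to carrying
capacity):

    c_t = D ∂²/∂x²[(α/α₀) c] + b (β/β₀) c (1−c)
    n_t = D_n n_xx + h₁ v (n₀ − n) − h₂ c n
    v_t = D_v v_xx + g₁ H(n − n₀) v (1−v) − g₂ v c^δ

with the motility/proliferation switch α(n) = (λ₁−n)/((λ₂−1)n+λ₁),
β(n) = λ₂n/((λ₂−1)n+λ₁) (hypoxic cells migrate, normoxic cells
proliferate; α₀, β₀ are the values at n = 1), and the decreasing
sigmoid H(z) = 1/(1+exp(kz)) opening the angiogenic switch under
hypoxia.  The transport term is implemented literally as the Laplacian
of (α/α₀)c, not in divergence form.  No-flux boundaries at both ends;
initial conditions are a sigmoid tumor seed of length ε at x = 0,
uniform oxygen n₀ and vasculature v₀.  Setting the oxygen to its
normoxic value reduces the tumor equation to the Fisher-Kolmogorov
(FK) equation c_t = D c_xx + b c(1−c), which is the deliberately
simplified prior model of the benchmark.

**Clinical outputs.** IW = x(2% crossing) − x(80% crossing) of the
maximum density, each located by linear interpolation on the rightmost
descending front (the tumor is seeded at x = 0 and invades rightward);
TS = ∫c dx / max(c) by trapezoidal quadrature, with TS = 0 for an empty
profile.  Profiles with no descending crossing raise a front error.
The unmodelable summaries are the plain tissue integrals n̄ = ∫n dx,
v̄ = ∫v dx (unnormalized by L; a normalized variant would only rescale
the KDE axes).

**Parameter defaults (reconstructions).** The source literature for
this model family does not fix a single parameter table, so the
defaults here are package choices at a physiological scale, in months
and millimetres: D, b ∈ [0.3, 3] (≈0.01–0.1 mm²/day and /day), oxygen
diffusivity D_n = 10 mm²/month, vascular D_v = 0.2, supply h₁ = 10,
consumption h₂ = 20, angiogenesis g₁ = 0.4, occlusion g₂ = 0.15 per
month, occlusion exponent δ = 1 (simplest choice, configurable),
λ₁ = 1.5, λ₂ = 2 (α amplification ≤ 5 under full hypoxia), n₀ = 0.5,
c₀ = 0.8, v₀ = 0.5, ε = 10 mm, sigmoid constant k = 10.  Every
benchmark reads these and the five sampled ranges from its config.

**Numerics.** Method of lines with second-order central differences and
a mirror-ghost closure of the no-flux conditions (which conserves the
trapezoidal mass of a purely diffusing field to rounding); explicit
Heun (RK2) stepping with Δt = min(0.4 · stability bound, 0.05 months).
The 0.05-month cap keeps the temporal truncation error below ≈10⁻⁴
relative even when the stability bound is loose (reaction-dominated
runs); the FK-vs-logistic closed-form test pins this accuracy.
Reference grid: L = 400 mm with 401 nodes (1 mm spacing).  The domain
is long enough that the fastest-growing virtual patients keep an
interior 2% front through the 36-month horizon, and halving the spacing
changes IW and TS by < 1% (0.85% and 0.3% measured at the reference
parameter set).  Cohorts and parameter sweeps integrate as one batched
array sharing the worst-case step, which is what makes 10 replicates ×
50 patients × 400 FK runs tractable on one CPU.

## 3. The virtual-cohort benchmark

Virtual patients are drawn by sampling five full-model parameters —
D, b, h₁, g₁, g₂ — i.i.d. uniform over the configured ranges
(D, b ∈ [0.3, 3], h₁ ∈ [5, 20], g₁ ∈ [0.15, 0.6], g₂ ∈ [0.05, 0.3]);
all patients share the initial condition, and each is integrated for 36
months with all variables stored monthly.  The ensemble table records
(IW, TS, n̄, v̄) at a per-patient diagnosis time drawn uniformly on
integer months in [t₀−6, t₀+6] (integer months because trajectories are
stored monthly; clamped to ≥ 1).  For each patient and prediction
horizon, the FK prior runs from c(x, t₀) over a 20 × 20 (D, b) lattice
spanning the same ranges the cohort was sampled from, the KDE is
conditioned on the patient's (n̄, v̄) at t₀ — by default including the
patient's own ensemble row, with a leave-one-out switch — and the
ground truth is the full model's outputs at t₀ + t_p.  Scoring uses
d_k = √((1/N_y) Σ (1−⟨y⟩/yʳ)²) over the N_y = 2 outputs (the
normalizer is the output count, which keeps d dimensionless and
consistent with the per-output partial errors), and classifies with
ε = 0.05: |d_b − d_m| ≤ ε d_m unchanged, above improved/deteriorated
accordingly.  Replicate runs spawn independent seed streams from one
root seed; a benchmark is fully determined by (config, seed).

At the reference conditions (t₀ = 24 months, t_p ∈ {6, 9, 12}, ten
replicates of N = 50) the fusion improves ≈99% of patients.  The
mechanism matches the design: the FK prior sweeps the full population
parameter range and is therefore broad and biased for any individual,
while the unmodelables at late presentation correlate strongly with the
eventual outputs, so the data density re-centers the posterior.  Mode
scoring (with the multi-peak convention of averaging the relative
errors over the retained peaks) is available alongside expected-value
scoring.

## 4. B-CLL labeled-cell kinetics

The labeled fraction follows the two-compartment solution

    f(t) = h(t) + f(0) e^{−bt/v_r}
         + e^{−bt/v_r} (g(0) − h(t))/(v_r − 1)
         + e^{−bt}      (h(t) − g(0))/(v_r − 1)

with birth rate b, relative compartment size v_r (the printed solution
is singular at v_r = 1; the package raises there rather than taking the
limit), and body-water label concentration h(t).  The shape of h is not
fixed by the two-compartment solution itself; the package reconstructs
it as single-exponential uptake toward the intake plateau during
labeling (84 days by default) and exponential washout afterwards, both
at rate f_w.  On the default box b ∈ [0.004, 0.04]/day,
v_r ∈ [1.5, 12], f_w ∈ [0.02, 0.12]/day, f stays in [0, 1] (property
tested by sampling).  The f₅₀ model density is the normalized histogram
of f(50) over the (b, v_r, f_w) lattice.

The synthetic 17-patient table generator plants associations by mapping
a weighted sum of standardized unmodelables (CD38, age, WBC growth
rate, V_H status) through a logistic onto the birth-rate range.  The
incremental pipeline fuses the f₅₀ prior with KDEs over progressively
more unmodelables and reports the MSE of the highest-mode prediction;
with informative unmodelables the MSE decreases monotonically.  The KDE
is trained on the full table by default (the emulated protocol
estimates the density on the same cohort it predicts); a leave-one-out
switch removes that reuse.

## 5. Ovarian sensitive/resistant relapse model

Ṡ = (γ − δ(t) − τ) S and Ṙ = (γ − λδ(t)) R + τ S with net growth γ,
chemotherapy kill δ (= δ₀ during chemotherapy, 0 otherwise), mutation
τ and resistant-kill reduction λ.  Each constant-δ phase integrates in
closed form (with the t·e^{rt} limit at equal exponents, verified
against numerical integration to 10⁻⁸ relative); surgery multiplies
both populations by β ∈ (0, 1) — the alternative readings T → (1−β)T
or T → T/β of "reducing the volume by a factor β" are available as a
config switch.  Post-therapy the total grows exactly exponentially at
rate γ, and relapse is the bracketed, bisected first time the total
reaches T_R (relative tolerance 10⁻⁶; TtR reported in months, rates per
day).  Defaults (config values at clinical scale): γ = 0.01/day
(≈10-week doubling), τ = 10⁻⁵/day, λ = 0.05, β = 0.05 (strong
debulking), T_R = 10¹⁰ cells, T_init = 5·10¹⁰, three 21-day NACT and
adjuvant cycles with δ active throughout each cycle.

The per-patient kill rate δ₀ is fitted by a monotone root-find matching
the model's first-cycle volume ratio to the observed one; the model
density over TtR sweeps x₀ ∈ (0.4, 0.9) and δ₀ either over the wide
uninformative range 0.1–10/day (nearly flat TtR density) or over ±40%
around the fitted cohort mean (sharp density; the entropy ordering is
tested).

**Synthetic cohort design.**  The 20-patient-style generator plants an
age effect on γ (slope 0.25 across the 40–75-year range) and gives
patients lognormal initial burdens (log-sd 0.8) and kill rates (log-sd
0.12) plus 5% observation noise on TtR.  These defaults deliberately
put comparable, complementary shares of the outcome variance into the
modelable channel (initial burden — known to the mechanistic sweep) and
the unmodelable channel (age — known to the KDE): that is the regime
the fusion method is designed for, and in it the fused MSE falls below
both single-source MSEs (verified across many seeds at n = 200; at
n = 20 sampling variability makes occasional inversions possible).
When one channel dominates the variance, fusion cannot be expected to
beat the better single source — a scenario property, not an
implementation one.

## 6. What the synthetic benchmarks do and do not show

The generators emulate the *structure* of the real cohorts (ensemble
sizes, variable lists, treatment schedules), not their measured values:
real-cohort error magnitudes are not reproducible without the external
patient tables and are out of scope.  Passing benchmarks show that the
fusion machinery is implemented correctly and behaves as designed in
the regime it targets (complementary information sources, late
presentation, equilibrated unmodelable distributions).  They do not
show that any particular real cohort satisfies those conditions; the
overlap diagnostic (marginal-density overlap between successive
presentation times) exists precisely to probe the stationarity
assumption on real data.

## 7. Known limitations

* 1-D spatial domain only; no imaging-derived initial conditions and no
  treatment terms in the glioma model.
* Gaussian-product KDE only; categorical unmodelables are not
  supported (V_H status enters the KDE as a 0/1 numeric column).
* Uniform parameter priors throughout; no correlated or empirical
  sampling.
* The tolerance-box density inherits the sweep lattice's granularity: a
  20 × 20 lattice caps the resolution of the model prior.
* Full-model fields are verified to stay within [−tol, 1+tol] but are
  not clipped; extreme user-supplied parameter combinations outside the
  documented ranges may violate the maximum principle numerically and
  raise.
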