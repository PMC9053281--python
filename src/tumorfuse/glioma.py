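"""Glioma growth dynamics on a 1-D domain.

Two mechanistic models live here:

* the *full model*: three coupled reaction-diffusion equations for tumor
  cell density ``c``, oxygen ``n`` and functional vasculature ``v``,
  with hypoxia-driven phenotypic plasticity (the motility/proliferation
  switch ``alpha(n)``/``beta(n)``), angiogenesis gated by a sigmoid of
  the oxygen deficit, and vaso-occlusion by tumor compression:

      dc/dt = D d²/dx²[(alpha/alpha0) c] + b (beta/beta0) c (1 - c)
      dn/dt = D_n d²n/dx² + h1 v (n0 - n) - h2 c n
      dv/dt = D_v d²v/dx² + g1 H(n - n0) v (1 - v) - g2 v c**delta

  where ``H(z) = 1/(1 + exp(k z))`` is a decreasing sigmoid, so the
  angiogenic switch opens under hypoxia (``n < n0``).  The transport
  term is the Laplacian of the product ``(alpha/alpha0) c`` — literally,
  not in divergence form.

* the *Fisher-Kolmogorov (FK) model*, the constant-oxygen reduction:

      dc/dt = D d²c/dx² + b c (1 - c)

Both are solved by the method of lines: second-order central differences,
mirror-ghost closure of the no-flux boundary conditions, and explicit
Euler stepping with a stability-bounded time step.  Batched variants
integrate many parameter sets (or many patients) as one array, which is
what makes the parameter sweeps of the fusion step affordable.

Units: lengths in mm, times in months, rates in 1/month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .grids import Grid1D, SpatialState

__all__ = [
    "FullModelParams",
    "FkParams",
    "ClinicalOutputs",
    "FrontError",
    "IntegrationError",
    "sigmoid_h",
    "motility_switch",
    "simulate_full_model",
    "simulate_full_model_batch",
    "simulate_fk",
    "simulate_fk_batch",
    "infiltration_width",
    "tumor_size",
    "unmodelable_summaries",
]

#: Safety factor applied to the explicit stability bound.
_CFL_SAFETY = 0.4

#: Absolute cap on the time step (months): keeps the O(dt^2) Heun
#: truncation error small even when the stability bound is loose
#: (e.g. reaction-dominated runs at D ~ 0).
_DT_CAP = 0.05

#: Fractions of the maximum density defining the infiltration front.
IW_UPPER_FRACTION = 0.80
IW_LOWER_FRACTION = 0.02


class FrontError(ValueError):
    """The density profile has no well-defined invading front."""


class IntegrationError(RuntimeError):
    """The time integration produced non-finite values."""


def sigmoid_h(x, x0: float, steepness: float):
    """Decreasing sigmoid ``H(x - x0) = 1 / (1 + exp(k (x - x0)))``.

    Value 1/2 at ``x = x0``; tends to 1 for ``x << x0`` and to 0 for
    ``x >> x0``.  Evaluated through :func:`scipy.special.expit` so large
    arguments never overflow.
    """
    if steepness <= 0:
        raise ValueError(f"steepness must be positive, got {steepness}")
    return expit(-steepness * (np.asarray(x, dtype=float) - x0))


def motility_switch(n, lambda1: float, lambda2: float):
    """Oxygen-dependent motility and proliferation factors.

    alpha(n) = (lambda1 - n) / ((lambda2 - 1) n + lambda1)
    beta(n)  =  lambda2 n    / ((lambda2 - 1) n + lambda1)

    alpha decreases with oxygen (hypoxic cells migrate), beta increases
    (normoxic cells proliferate).  At ``n = 1`` the pair ``(alpha0,
    beta0)`` normalizes the full-model transport and growth terms.
    """
    _check_switch_denominator(lambda1, lambda2)
    n = np.asarray(n, dtype=float)
    denom = (lambda2 - 1.0) * n + lambda1
    return (lambda1 - n) / denom, lambda2 * n / denom


def _check_switch_denominator(lambda1: float, lambda2: float) -> None:
    # denom(n) = (lambda2 - 1) n + lambda1 is affine: checking the two
    # endpoints of n in [0, 1] suffices.
    d0, d1 = lambda1, (lambda2 - 1.0) + lambda1
    if d0 == 0 or d1 == 0 or np.sign(d0) != np.sign(d1):
        raise ValueError(
            "motility-switch denominator (lambda2 - 1) n + lambda1 vanishes "
            f"on n in [0, 1] for lambda1={lambda1}, lambda2={lambda2}"
        )


@dataclass(frozen=True)
class FullModelParams:
    """Parameters of the full hypoxia-plasticity model.

    Rates are per month, diffusivities mm²/month.  The defaults are the
    package's reference parametrization (see docs/methods.md for the
    rationale behind each value); the cohort generator varies ``D``,
    ``b``, ``h1``, ``g1`` and ``g2`` around them.
    """

    D: float = 1.0          # baseline tumor motility
    b: float = 1.0          # baseline proliferation rate
    D_n: float = 10.0       # oxygen diffusivity
    D_v: float = 0.2        # vascular diffusivity
    h1: float = 10.0        # oxygen supply rate (via vasculature)
    h2: float = 20.0        # oxygen consumption rate by tumor cells
    g1: float = 0.4         # angiogenesis rate
    g2: float = 0.15        # vaso-occlusion rate
    delta_exp: float = 1.0  # exponent on c in the occlusion term
    lambda1: float = 1.5    # motility-switch offset
    lambda2: float = 2.0    # proliferation-switch gain
    n0: float = 0.5         # hypoxic oxygen threshold = initial oxygen
    c0: float = 0.8         # initial tumor density in the seeded segment
    v0: float = 0.5         # initial vascular density
    eps_ic: float = 10.0    # initial tumor segment length (mm)
    sigmoid_steepness: float = 10.0  # sigmoid constant k > 0

    def validate(self, grid: Grid1D | None = None) -> None:
        for name in ("D", "b", "D_n", "D_v", "h1", "h2", "g1", "g2"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if not (0.0 < self.n0 <= 1.0):
            raise ValueError(f"n0 must be in (0, 1], got {self.n0}")
        for name in ("c0", "v0"):
            val = getattr(self, name)
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        if self.sigmoid_steepness <= 0:
            raise ValueError("sigmoid_steepness must be positive")
        if grid is not None and not (0.0 < self.eps_ic < grid.length):
            raise ValueError(
                f"eps_ic must lie inside (0, L={grid.length}), got {self.eps_ic}"
            )
        _check_switch_denominator(self.lambda1, self.lambda2)

    def initial_state(self, grid: Grid1D) -> SpatialState:
        """Initial conditions: a sigmoid tumor seed of length ``eps_ic``
        at the left end, uniform oxygen ``n0`` and vasculature ``v0``."""
        self.validate(grid)
        c = self.c0 * sigmoid_h(grid.x, self.eps_ic, self.sigmoid_steepness)
        n = np.full(grid.n_nodes, self.n0)
        v = np.full(grid.n_nodes, self.v0)
        return SpatialState(c=c, n=n, v=v, t=0.0)

    def alpha0_beta0(self) -> tuple[float, float]:
        a0, b0 = motility_switch(1.0, self.lambda1, self.lambda2)
        return float(a0), float(b0)


@dataclass(frozen=True)
class FkParams:
    """Fisher-Kolmogorov parameters: motility ``D`` (mm²/month) and
    proliferation rate ``b`` (1/month)."""

    D: float
    b: float

    def __post_init__(self) -> None:
        if self.D < 0 or self.b < 0:
            raise ValueError(f"D and b must be >= 0, got D={self.D}, b={self.b}")


@dataclass(frozen=True)
class ClinicalOutputs:
    """The two clinical outputs: infiltration width and tumor size (mm)."""

    IW: float
    TS: float

    def as_array(self) -> np.ndarray:
        return np.array([self.IW, self.TS])


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------

def _laplacian(a: np.ndarray, dx: float) -> np.ndarray:
    """Second-order Laplacian with mirror-ghost no-flux closure.

    Works on the last axis, so a batch of profiles ``(P, nx)`` is one call.
    """
    out = np.empty_like(a)
    out[..., 1:-1] = a[..., :-2] - 2.0 * a[..., 1:-1] + a[..., 2:]
    out[..., 0] = 2.0 * (a[..., 1] - a[..., 0])
    out[..., -1] = 2.0 * (a[..., -2] - a[..., -1])
    out /= dx * dx
    return out


def _save_times(t_end: float, save_every: float) -> np.ndarray:
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if save_every <= 0:
        raise ValueError(f"save_every must be positive, got {save_every}")
    n = int(round(t_end / save_every))
    if not np.isclose(n * save_every, t_end):
        n = int(np.ceil(t_end / save_every - 1e-12))
    times = save_every * np.arange(1, n + 1)
    times[-1] = min(times[-1], t_end)
    return times


# ---------------------------------------------------------------------------
# Fisher-Kolmogorov solver
# ---------------------------------------------------------------------------

def simulate_fk_batch(
    c_init: np.ndarray,
    D: np.ndarray,
    b: np.ndarray,
    grid: Grid1D,
    save_times: Sequence[float],
) -> np.ndarray:
    """Integrate the FK equation for many ``(D, b)`` pairs at once.

    Parameters
    ----------
    c_init
        Either one profile ``(nx,)`` shared by all parameter sets, or a
        batch ``(P, nx)``.
    D, b
        Arrays of shape ``(P,)``.
    save_times
        Strictly increasing positive times (months) at which to record
        the profile.

    Returns
    -------
    ndarray of shape ``(n_save, P, nx)``.
    """
    D = np.atleast_1d(np.asarray(D, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if D.shape != b.shape:
        raise ValueError("D and b must have the same shape")
    P = D.size
    c_init = np.asarray(c_init, dtype=float)
    if c_init.ndim == 1:
        c = np.broadcast_to(c_init, (P, c_init.size)).copy()
    else:
        c = c_init.copy()
        if c.shape[0] != P:
            raise ValueError("batched c_init must match parameter count")
    save_times = np.asarray(save_times, dtype=float)
    if save_times.size and (np.any(np.diff(save_times) <= 0) or save_times[0] < 0):
        raise ValueError("save_times must be non-negative and increasing")

    dx = grid.dx
    bounds = [_DT_CAP]
    if D.max() > 0:
        bounds.append(_CFL_SAFETY * dx * dx / (2.0 * D.max()))
    if b.max() > 0:
        bounds.append(_CFL_SAFETY / b.max())
    dt_max = min(bounds)

    Dcol = D[:, None]
    bcol = b[:, None]

    def rhs(u: np.ndarray) -> np.ndarray:
        return Dcol * _laplacian(u, dx) + bcol * u * (1.0 - u)

    out = np.empty((save_times.size, P, c.shape[1]))
    t = 0.0
    for k, t_target in enumerate(save_times):
        span = t_target - t
        if span > 0:
            nsteps = max(1, int(np.ceil(span / dt_max)))
            dt = span / nsteps
            for _ in range(nsteps):
                k1 = rhs(c)
                k2 = rhs(c + dt * k1)
                c += 0.5 * dt * (k1 + k2)
            t = t_target
        if not np.all(np.isfinite(c)):
            raise IntegrationError(f"FK integration diverged by t = {t_target:g} months")
        out[k] = c
    return out


def simulate_fk(
    c_init: np.ndarray, params: FkParams, grid: Grid1D, duration: float
) -> np.ndarray:
    """Integrate the FK equation for one parameter set; returns ``c`` at
    ``t = duration`` (``duration = 0`` returns the input unchanged)."""
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    c_init = np.asarray(c_init, dtype=float)
    if c_init.shape != (grid.n_nodes,):
        raise ValueError("c_init does not match the grid")
    if duration == 0:
        return c_init.copy()
    out = simulate_fk_batch(c_init, [params.D], [params.b], grid, [duration])
    return out[-1, 0]


# ---------------------------------------------------------------------------
# full-model solver
# ---------------------------------------------------------------------------

def _full_model_dt(
    params: FullModelParams,
    D: np.ndarray,
    b: np.ndarray,
    h1: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    dx: float,
) -> float:
    """Explicit-Euler stability bound for the batched full model."""
    a0, b0 = params.alpha0_beta0()
    n_probe = np.linspace(0.0, 1.0, 64)
    alpha, beta = motility_switch(n_probe, params.lambda1, params.lambda2)
    amp = float(np.max(np.abs(alpha))) / a0
    beta_max = float(np.max(np.abs(beta))) / b0

    bounds = [np.inf]
    diff_max = max(float(D.max()) * amp, params.D_n, params.D_v)
    if diff_max > 0:
        bounds.append(dx * dx / (2.0 * diff_max))
    rate_max = max(
        float(b.max()) * beta_max,
        float(h1.max()),
        params.h2,
        float(g1.max()),
        float(g2.max()),
    )
    if rate_max > 0:
        bounds.append(1.0 / rate_max)
    return min(_CFL_SAFETY * min(bounds), _DT_CAP)


def simulate_full_model_batch(
    initial: SpatialState,
    params: FullModelParams,
    grid: Grid1D,
    varied: dict[str, np.ndarray],
    save_times: Sequence[float],
) -> dict[str, np.ndarray]:
    """Integrate the full model for a batch of patients sharing the grid,
    the initial state and all parameters except those in ``varied``.

    ``varied`` may override ``D``, ``b``, ``h1``, ``g1``, ``g2`` with
    per-patient arrays of shape ``(P,)``.  Returns ``{"c", "n", "v"}``
    arrays of shape ``(n_save, P, nx)``.
    """
    allowed = {"D", "b", "h1", "g1", "g2"}
    if not set(varied) <= allowed:
        raise ValueError(f"varied keys must be among {sorted(allowed)}")
    sizes = {np.asarray(v).size for v in varied.values()} or {1}
    if len(sizes) != 1:
        raise ValueError("all varied arrays must share one length")
    P = sizes.pop()

    def _col(name: str) -> np.ndarray:
        arr = np.asarray(varied.get(name, getattr(params, name)), dtype=float)
        return np.broadcast_to(arr, (P,)).astype(float)

    D, b, h1, g1, g2 = (_col(k) for k in ("D", "b", "h1", "g1", "g2"))
    params.validate(grid)
    initial.validate(grid)

    dx = grid.dx
    dt_max = _full_model_dt(params, D, b, h1, g1, g2, dx)
    a0, b0 = params.alpha0_beta0()

    c = np.broadcast_to(initial.c, (P, grid.n_nodes)).copy()
    n = np.broadcast_to(initial.n, (P, grid.n_nodes)).copy()
    v = np.broadcast_to(initial.v, (P, grid.n_nodes)).copy()
    Dc, bc = D[:, None], b[:, None]
    h1c, g1c, g2c = h1[:, None], g1[:, None], g2[:, None]

    save_times = np.asarray(save_times, dtype=float)
    out_c = np.empty((save_times.size, P, grid.n_nodes))
    out_n = np.empty_like(out_c)
    out_v = np.empty_like(out_c)

    t = initial.t
    for k, t_target in enumerate(save_times):
        span = t_target - t
        if span < -1e-12:
            raise ValueError("save_times must not precede the initial time")
        if span > 0:
            nsteps = max(1, int(np.ceil(span / dt_max)))
            dt = span / nsteps

            def rhs(cu, nu, vu):
                alpha, beta = motility_switch(nu, params.lambda1, params.lambda2)
                hyp = sigmoid_h(nu, params.n0, params.sigmoid_steepness)
                c_pos = np.clip(cu, 0.0, None)
                dc = Dc * _laplacian((alpha / a0) * cu, dx) + bc * (beta / b0) * cu * (1.0 - cu)
                dn = params.D_n * _laplacian(nu, dx) + h1c * vu * (params.n0 - nu) - params.h2 * cu * nu
                dv = (
                    params.D_v * _laplacian(vu, dx)
                    + g1c * hyp * vu * (1.0 - vu)
                    - g2c * vu * c_pos ** params.delta_exp
                )
                return dc, dn, dv

            for _ in range(nsteps):
                k1c, k1n, k1v = rhs(c, n, v)
                k2c, k2n, k2v = rhs(c + dt * k1c, n + dt * k1n, v + dt * k1v)
                c += 0.5 * dt * (k1c + k2c)
                n += 0.5 * dt * (k1n + k2n)
                v += 0.5 * dt * (k1v + k2v)
            t = t_target
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(n)) and np.all(np.isfinite(v))):
            raise IntegrationError(
                f"full-model integration diverged by t = {t_target:g} months"
            )
        out_c[k], out_n[k], out_v[k] = c, n, v
    return {"c": out_c, "n": out_n, "v": out_v}


def simulate_full_model(
    initial: SpatialState,
    params: FullModelParams,
    grid: Grid1D,
    t_end: float,
    save_every: float = 1.0,
) -> list[SpatialState]:
    """Integrate the full model from ``initial`` and return states at
    ``save_every, 2 save_every, ..., t_end`` (initial state not repeated)."""
    times = _save_times(t_end, save_every)
    out = simulate_full_model_batch(initial, params, grid, {}, times)
    return [
        SpatialState(out["c"][k, 0], out["n"][k, 0], out["v"][k, 0], t=float(tk))
        for k, tk in enumerate(times)
    ]


# ---------------------------------------------------------------------------
# clinical outputs
# ---------------------------------------------------------------------------

def _rightmost_descending_crossing(
    c: np.ndarray, x: np.ndarray, threshold: float
) -> float:
    above = c >= threshold
    idx = np.nonzero(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        raise FrontError(
            f"density never descends through {threshold:.4g}: no invading front"
        )
    i = idx[-1]
    # linear interpolation between nodes i and i+1
    return float(x[i] + (c[i] - threshold) / (c[i] - c[i + 1]) * (x[i + 1] - x[i]))


def infiltration_width(c: np.ndarray, grid: Grid1D) -> float:
    """Infiltration width: distance between the points where the density
    falls to 80% and to 2% of its maximum, located by linear
    interpolation on the rightmost descending front."""
    c = np.asarray(c, dtype=float)
    cmax = c.max()
    if cmax <= 0:
        raise FrontError("density is identically zero: no front")
    x = grid.x
    x_hi = _rightmost_descending_crossing(c, x, IW_UPPER_FRACTION * cmax)
    x_lo = _rightmost_descending_crossing(c, x, IW_LOWER_FRACTION * cmax)
    return x_lo - x_hi


def tumor_size(c: np.ndarray, grid: Grid1D) -> float:
    """Tumor size: integral of the density profile divided by its maximum
    (trapezoidal quadrature); 0 for an empty profile."""
    c = np.asarray(c, dtype=float)
    cmax = c.max()
    if cmax <= 0:
        return 0.0
    return float(np.trapezoid(c, grid.x) / cmax)


def clinical_outputs(c: np.ndarray, grid: Grid1D) -> ClinicalOutputs:
    return ClinicalOutputs(IW=infiltration_width(c, grid), TS=tumor_size(c, grid))


def unmodelable_summaries(state: SpatialState, grid: Grid1D) -> tuple[float, float]:
    """Tissue integrals of oxygen and vasculature, ``(n_bar, v_bar)``,
    by trapezoidal quadrature (unnormalized by domain length)."""
    return (
        float(np.trapezoid(state.n, grid.x)),
        float(np.trapezoid(state.v, grid.x)),
    )
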