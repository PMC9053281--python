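"""Unit tests for the glioma PDE system, its FK reduction and the
clinical-output extractors, checked against closed forms and
independent scalar-ODE oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tumorfuse import (
    FkParams,
    FullModelParams,
    Grid1D,
    SpatialState,
    infiltration_width,
    motility_switch,
    sigmoid_h,
    simulate_fk,
    simulate_full_model,
    tumor_size,
    unmodelable_summaries,
)
from tumorfuse.glioma import FrontError, simulate_fk_batch, simulate_full_model_batch


class TestSigmoid:
    def test_midpoint_is_half(self):
        assert sigmoid_h(3.2, 3.2, 17.0) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert sigmoid_h(-1e6, 0.0, 1.0) == pytest.approx(1.0)
        assert sigmoid_h(1e6, 0.0, 1.0) == pytest.approx(0.0)

    def test_quarter_point(self):
        # 1 / (1 + e^{ln 3}) = 1/4
        assert sigmoid_h(np.log(3.0), 0.0, 1.0) == pytest.approx(0.25, abs=1e-12)

    def test_overflow_safe(self):
        with np.errstate(over="raise"):
            val = sigmoid_h(1e4, 0.0, 100.0)
        assert val == 0.0

    def test_rejects_nonpositive_steepness(self):
        with pytest.raises(ValueError):
            sigmoid_h(0.0, 0.0, 0.0)


class TestMotilitySwitch:
    def test_normoxic_values(self):
        l1, l2 = 1.5, 2.0
        alpha, beta = motility_switch(1.0, l1, l2)
        assert alpha == pytest.approx((l1 - 1) / (l2 - 1 + l1))
        assert beta == pytest.approx(l2 / (l2 - 1 + l1))

    def test_zeros_of_numerators(self):
        alpha, _ = motility_switch(0.9, 0.9, 2.0)
        assert alpha == pytest.approx(0.0)
        _, beta = motility_switch(0.0, 1.5, 2.0)
        assert beta == pytest.approx(0.0)

    def test_degenerate_denominator_rejected(self):
        # denominator changes sign on [0, 1]
        with pytest.raises(ValueError):
            motility_switch(0.5, 0.5, 0.0)


class TestFkSolver:
    def test_frozen_dynamics_identity(self, ref_grid):
        c0 = np.exp(-((ref_grid.x - 50.0) ** 2) / 100.0)
        out = simulate_fk(c0, FkParams(D=0.0, b=0.0), ref_grid, 5.0)
        np.testing.assert_allclose(out, c0, rtol=1e-12)

    def test_zero_duration_returns_input(self, ref_grid):
        c0 = np.linspace(0, 1, ref_grid.n_nodes)
        out = simulate_fk(c0, FkParams(D=1.0, b=1.0), ref_grid, 0.0)
        np.testing.assert_array_equal(out, c0)

    def test_pointwise_logistic_at_zero_diffusion(self, ref_grid):
        # with D = 0 every node follows the logistic closed form
        cstar, b, t = 0.2, 0.8, 4.0
        c0 = np.full(ref_grid.n_nodes, cstar)
        out = simulate_fk(c0, FkParams(D=0.0, b=b), ref_grid, t)
        expected = cstar * np.exp(b * t) / (1.0 + cstar * (np.exp(b * t) - 1.0))
        np.testing.assert_allclose(out, expected, rtol=1e-4)

    def test_mass_conserved_under_pure_diffusion(self, ref_grid):
        c0 = np.exp(-((ref_grid.x - 150.0) ** 2) / 200.0)
        mass0 = np.trapezoid(c0, ref_grid.x)
        out = simulate_fk(c0, FkParams(D=2.0, b=0.0), ref_grid, 12.0)
        mass1 = np.trapezoid(out, ref_grid.x)
        assert abs(mass1 - mass0) / mass0 < 1e-6

    def test_batch_matches_single_runs(self, ref_grid):
        c0 = np.exp(-((ref_grid.x - 50.0) ** 2) / 400.0)
        D = np.array([0.5, 2.0])
        b = np.array([0.3, 1.5])
        batch = simulate_fk_batch(c0, D, b, ref_grid, [3.0, 6.0])
        for j in range(2):
            single = simulate_fk(c0, FkParams(D[j], b[j]), ref_grid, 6.0)
            np.testing.assert_allclose(batch[1, j], single, rtol=1e-10)


class TestFullModel:
    def test_empty_tumor_leaves_oxygen_fixed_and_vessels_logistic(self, ref_grid):
        # with c = 0 the oxygen equation is at equilibrium and the
        # vessel equation reduces to a scalar logistic ODE with
        # effective rate g1 * H(0) = g1 / 2
        params = FullModelParams()
        state = SpatialState(
            c=np.zeros(ref_grid.n_nodes),
            n=np.full(ref_grid.n_nodes, params.n0),
            v=np.full(ref_grid.n_nodes, params.v0),
        )
        states = simulate_full_model(state, params, ref_grid, t_end=12.0, save_every=3.0)
        rate = params.g1 * 0.5
        sol = solve_ivp(
            lambda t, y: rate * y * (1 - y), (0, 12.0), [params.v0],
            t_eval=[s.t for s in states], rtol=1e-10, atol=1e-12,
        )
        for k, s in enumerate(states):
            np.testing.assert_allclose(s.c, 0.0, atol=1e-14)
            np.testing.assert_allclose(s.n, params.n0, atol=1e-10)
            np.testing.assert_allclose(s.v, sol.y[0][k], rtol=2e-3)
        assert all(
            states[k + 1].v[0] > states[k].v[0] for k in range(len(states) - 1)
        )

    def test_reduces_to_fk_at_constant_oxygen(self, ref_grid):
        # h2 = 0 and n = n0 initially: oxygen never moves and the tumor
        # equation is exactly FK with rescaled D and b
        params = FullModelParams(h2=0.0, D=1.0, b=1.0)
        state = params.initial_state(ref_grid)
        out = simulate_full_model(state, params, ref_grid, t_end=6.0, save_every=6.0)
        a0, b0 = params.alpha0_beta0()
        alpha, beta = motility_switch(params.n0, params.lambda1, params.lambda2)
        fk = simulate_fk(
            state.c,
            FkParams(D=params.D * float(alpha) / a0, b=params.b * float(beta) / b0),
            ref_grid,
            6.0,
        )
        assert np.max(np.abs(out[-1].c - fk)) < 1e-3

    def test_mass_conserved_with_pure_diffusion(self, ref_grid):
        params = FullModelParams(b=0.0, h1=0.0, h2=0.0, g1=0.0, g2=0.0, D=1.5)
        state = params.initial_state(ref_grid)
        mass0 = np.trapezoid(state.c, ref_grid.x)
        out = simulate_full_model(state, params, ref_grid, t_end=12.0, save_every=12.0)
        # oxygen is uniform so alpha is constant: the transport term is a
        # plain Laplacian and mass under no-flux must not drift
        mass1 = np.trapezoid(out[-1].c, ref_grid.x)
        assert abs(mass1 - mass0) / mass0 < 1e-6

    def test_fields_stay_in_unit_range(self, ref_grid):
        params = FullModelParams()
        state = params.initial_state(ref_grid)
        states = simulate_full_model(state, params, ref_grid, t_end=24.0, save_every=6.0)
        for s in states:
            s.validate(ref_grid, tol=1e-3)

    def test_grid_refinement_converges(self):
        params = FullModelParams()
        vals = {}
        for nodes in (401, 801):
            grid = Grid1D(400.0, nodes)
            state = params.initial_state(grid)
            out = simulate_full_model(state, params, grid, t_end=12.0, save_every=12.0)
            vals[nodes] = (
                infiltration_width(out[-1].c, grid),
                tumor_size(out[-1].c, grid),
            )
        for a, b in zip(vals[401], vals[801]):
            assert abs(a - b) / b < 0.01


class TestClinicalOutputs:
    def test_infiltration_width_hand_example(self, ref_grid):
        # plateau at 1 until x=100, linear down to 0 at x=200:
        # 80% crossing at x=120, 2% crossing at x=198, width 78
        x = ref_grid.x
        c = np.clip(1.0 - (x - 100.0) / 100.0, 0.0, 1.0)
        assert infiltration_width(c, ref_grid) == pytest.approx(78.0, abs=1e-9)

    def test_step_profile_width_below_one_spacing(self, ref_grid):
        c = np.where(ref_grid.x <= 150.0, 1.0, 0.0)
        assert 0 < infiltration_width(c, ref_grid) <= ref_grid.dx

    def test_uniform_profile_has_no_front(self, ref_grid):
        with pytest.raises(FrontError):
            infiltration_width(np.full(ref_grid.n_nodes, 0.4), ref_grid)
        with pytest.raises(FrontError):
            infiltration_width(np.zeros(ref_grid.n_nodes), ref_grid)

    def test_tumor_size_examples(self, ref_grid):
        assert tumor_size(np.full(ref_grid.n_nodes, 0.5), ref_grid) == pytest.approx(300.0)
        tri = np.clip(1.0 - ref_grid.x / 100.0, 0.0, None)
        assert tumor_size(tri, ref_grid) == pytest.approx(50.0)
        assert tumor_size(np.zeros(ref_grid.n_nodes), ref_grid) == 0.0

    def test_outputs_invariant_under_density_rescaling(self, ref_grid):
        c = np.exp(-((ref_grid.x - 80.0) ** 2) / 500.0)
        for scale in (0.3, 2.0):
            assert infiltration_width(scale * c, ref_grid) == pytest.approx(
                infiltration_width(c, ref_grid)
            )
            assert tumor_size(scale * c, ref_grid) == pytest.approx(
                tumor_size(c, ref_grid)
            )

    def test_unmodelable_summaries(self, ref_grid):
        L = ref_grid.length
        state = SpatialState(
            c=np.zeros(ref_grid.n_nodes),
            n=np.full(ref_grid.n_nodes, 0.5),
            v=np.zeros(ref_grid.n_nodes),
        )
        n_bar, v_bar = unmodelable_summaries(state, ref_grid)
        assert n_bar == pytest.approx(0.5 * L)
        assert v_bar == 0.0
        state.n = ref_grid.x / L  # linear 0 -> 1
        n_bar, _ = unmodelable_summaries(state, ref_grid)
        assert n_bar == pytest.approx(L / 2.0)


def test_batch_full_model_matches_single(ref_grid):
    params = FullModelParams()
    state = params.initial_state(ref_grid)
    varied = {"D": np.array([0.5, 2.0]), "b": np.array([0.4, 1.2])}
    batch = simulate_full_model_batch(state, params, ref_grid, varied, [6.0])
    for j in range(2):
        p = FullModelParams(**{**params.__dict__, "D": varied["D"][j], "b": varied["b"][j]})
        single = simulate_full_model(state, p, ref_grid, t_end=6.0, save_every=6.0)
        np.testing.assert_allclose(batch["c"][0, j], single[-1].c, rtol=1e-8, atol=1e-10)
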