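"""Fusion-layer tests: Silverman bandwidths, the tolerance-box model
pdf against a double-loop counting oracle, the conditional KDE against
a brute-force kernel sum, the fusion rule's algebra, and the pdf
summaries against closed forms."""

import numpy as np
import pandas as pd
import pytest

from tumorfuse import (
    PdfGrid,
    effective_variance,
    fuse_pdfs,
    kde_conditioned_pdf,
    pdf_expected_value,
    pdf_modes,
    silverman_bandwidths,
)
from tumorfuse.fusion import (
    IncompatibleEvidenceError,
    build_output_grid,
    histogram_pdf,
    pdf_entropy,
    tolerance_box_pdf,
)


def discrete_gaussian(axes, means, variances):
    vals = np.exp(
        -0.5 * (axes[0][:, None] - means[0]) ** 2 / variances[0]
        - 0.5 * (axes[1][None, :] - means[1]) ** 2 / variances[1]
    )
    return PdfGrid(axes, vals, axis_names=("IW", "TS")).normalize()


class TestSilverman:
    def test_two_point_hand_value(self):
        bw = silverman_bandwidths(np.array([[0.0], [2.0]]))
        expected = np.sqrt(2.0) * (4.0 / 6.0) ** 0.2
        assert bw.h[0] == pytest.approx(expected, rel=1e-12)

    def test_cohort_scale_factor(self, rng):
        # d = 4, n = 500 with unit sample sd per column:
        # h = (4 / 3000)^{1/8} per dimension
        z = rng.normal(size=(500, 4))
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
        bw = silverman_bandwidths(z)
        np.testing.assert_allclose(bw.h, (4.0 / 3000.0) ** 0.125, rtol=1e-12)

    def test_scales_linearly_with_column(self, rng):
        data = rng.normal(size=(40, 2))
        doubled = data.copy()
        doubled[:, 1] *= 2.0
        a, b = silverman_bandwidths(data), silverman_bandwidths(doubled)
        assert b.h[1] == pytest.approx(2.0 * a.h[1], rel=1e-12)
        assert b.h[0] == pytest.approx(a.h[0], rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            silverman_bandwidths(np.array([[1.0, 2.0]]))  # n = 1
        df = pd.DataFrame({"ok": [0.0, 1.0, 2.0], "flat": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            silverman_bandwidths(df)


class TestToleranceBox:
    def test_degenerate_single_outcome(self):
        outcome = np.array([[20.0, 100.0]])
        axes = (np.linspace(10, 30, 50), np.linspace(50, 150, 60))
        pdf = tolerance_box_pdf(outcome, axes, 0.05)
        assert pdf.total_mass() == pytest.approx(1.0, abs=1e-9)
        # support confined to grid points whose +/-5% box contains the outcome
        g1, g2 = np.meshgrid(axes[0], axes[1], indexing="ij")
        inside = (
            (0.95 * g1 < 20.0) & (20.0 < 1.05 * g1)
            & (0.95 * g2 < 100.0) & (100.0 < 1.05 * g2)
        )
        assert np.all(pdf.values[~inside] == 0)
        assert np.all(pdf.values[inside] > 0)

    def test_matches_double_loop_oracle(self, rng):
        outcomes = rng.uniform([5, 40], [25, 160], size=(9, 2))  # a 3x3 sweep
        axes = (np.linspace(4, 26, 21), np.linspace(30, 170, 17))
        pdf = tolerance_box_pdf(outcomes, axes, 0.05)
        counts = np.zeros((21, 17))
        for i, giw in enumerate(axes[0]):
            for j, gts in enumerate(axes[1]):
                for iw, ts in outcomes:
                    if 0.95 * giw < iw < 1.05 * giw and 0.95 * gts < ts < 1.05 * gts:
                        counts[i, j] += 1
        oracle = counts / (counts.sum() * pdf.cell_volume)
        np.testing.assert_allclose(pdf.values, oracle, rtol=1e-12, atol=1e-15)

    def test_invariant_to_sweep_ordering(self, rng):
        outcomes = rng.uniform([5, 40], [25, 160], size=(16, 2))
        axes = (np.linspace(4, 26, 15), np.linspace(30, 170, 15))
        a = tolerance_box_pdf(outcomes, axes)
        b = tolerance_box_pdf(outcomes[::-1], axes)
        np.testing.assert_array_equal(a.values, b.values)

    def test_outcomes_off_grid_raise(self):
        with pytest.raises(ValueError, match="extend the output grid"):
            tolerance_box_pdf(
                np.array([[1000.0, 1000.0]]),
                (np.linspace(1, 2, 5), np.linspace(1, 2, 5)),
            )


def kernel_sum_oracle(data, cond, axes):
    """Independent double loop: full product-kernel sum over rows and
    grid cells, then Riemann renormalization over the output grid."""
    sigma = data.std(axis=0, ddof=1)
    d, n = data.shape[1], data.shape[0]
    h = sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    k = len(axes)
    out = np.zeros(tuple(len(a) for a in axes))
    for idx in np.ndindex(out.shape):
        point = [axes[dim][idx[dim]] for dim in range(k)]
        total = 0.0
        for row in data:
            kern = 1.0
            for dim in range(k):
                kern *= np.exp(-0.5 * ((point[dim] - row[dim]) / h[dim]) ** 2)
            for dim in range(k, d):
                kern *= np.exp(-0.5 * ((cond[dim - k] - row[dim]) / h[dim]) ** 2)
            total += kern
        out[idx] = total
    vol = np.prod([a[1] - a[0] for a in axes])
    return out / (out.sum() * vol)


class TestConditionalKde:
    def test_matches_kernel_sum_oracle(self, rng):
        ensemble = pd.DataFrame(
            rng.uniform([10, 50, 100, 150], [30, 150, 300, 400], size=(15, 4)),
            columns=["IW", "TS", "n_bar", "v_bar"],
        )
        axes = (np.linspace(5, 35, 24), np.linspace(40, 160, 30))
        pdf = kde_conditioned_pdf(ensemble, (180.0, 220.0), axes)
        oracle = kernel_sum_oracle(
            ensemble.to_numpy(), np.array([180.0, 220.0]), axes
        )
        np.testing.assert_allclose(pdf.values, oracle, rtol=1e-10)
        assert pdf.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_near_duplicate_rows_put_mode_at_shared_outputs(self):
        ensemble = pd.DataFrame(
            {
                "IW": [20.0, 20.001],
                "TS": [100.0, 100.001],
                "n_bar": [150.0, 150.001],
                "v_bar": [200.0, 200.001],
            }
        )
        axes = (np.linspace(10, 30, 41), np.linspace(80, 120, 41))
        pdf = kde_conditioned_pdf(ensemble, (150.0, 200.0), axes)
        mode = pdf_modes(pdf)[0]
        assert abs(mode[0] - 20.0) <= pdf.spacings[0]
        assert abs(mode[1] - 100.0) <= pdf.spacings[1]

    def test_far_patient_follows_nearest_row(self, rng):
        ensemble = pd.DataFrame(
            {
                "IW": [15.0, 25.0, 20.0],
                "TS": [80.0, 140.0, 110.0],
                "n_bar": [100.0, 160.0, 130.0],
                "v_bar": [210.0, 260.0, 240.0],
            }
        )
        # conditioning point enormously far beyond the largest n_bar row:
        # that row's kernel dominates all others
        axes = (np.linspace(10, 30, 60), np.linspace(60, 160, 60))
        pdf = kde_conditioned_pdf(ensemble, (1e4, 1e4), axes)
        mode = pdf_modes(pdf)[0]
        assert abs(mode[0] - 25.0) <= pdf.spacings[0]
        assert abs(mode[1] - 140.0) <= pdf.spacings[1]


class TestFuseRule:
    def test_symmetry(self, rng):
        axes = (np.linspace(0, 1, 20), np.linspace(0, 2, 25))
        p = discrete_gaussian(axes, (0.4, 1.0), (0.02, 0.1))
        q = discrete_gaussian(axes, (0.6, 0.8), (0.05, 0.2))
        np.testing.assert_array_equal(
            fuse_pdfs(p, q).values, fuse_pdfs(q, p).values
        )

    def test_uniform_factor_reductions_bitwise_on_dyadic_fixture(self):
        # dyadic construction: cell volume 1/4, density values and the
        # uniform level are powers of two, so every renormalization is
        # an exact IEEE scaling and the reduction must be bit-for-bit
        axes = (np.arange(8) * 0.5, np.arange(8) * 0.5)
        vals = np.zeros((8, 8))
        vals[2, 3], vals[4, 4], vals[5, 1] = 2.0, 1.0, 1.0
        model = PdfGrid(axes, vals, normalized=True)  # mass = 4 * 0.25 = 1
        uniform = PdfGrid(axes, np.full((8, 8), 0.0625), normalized=True)
        np.testing.assert_array_equal(fuse_pdfs(model, uniform).values, model.values)
        np.testing.assert_array_equal(fuse_pdfs(uniform, model).values, model.values)

    def test_uniform_factor_reductions_generic(self):
        axes = (np.linspace(0, 1, 30), np.linspace(0, 3, 40))
        p = discrete_gaussian(axes, (0.5, 1.5), (0.03, 0.3))
        u = PdfGrid(axes, np.ones((30, 40))).normalize()
        np.testing.assert_allclose(fuse_pdfs(p, u).values, p.values, rtol=1e-12)
        np.testing.assert_allclose(fuse_pdfs(u, p).values, p.values, rtol=1e-12)

    def test_disjoint_supports_raise(self):
        axes = (np.linspace(0, 1, 10), np.linspace(0, 1, 10))
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[0, 0] = 1.0
        b[9, 9] = 1.0
        with pytest.raises(IncompatibleEvidenceError):
            fuse_pdfs(PdfGrid(axes, a).normalize(), PdfGrid(axes, b).normalize())

    def test_axis_mismatch_raises(self):
        a = PdfGrid((np.linspace(0, 1, 5),), np.ones(5)).normalize()
        b = PdfGrid((np.linspace(0, 2, 5),), np.ones(5)).normalize()
        with pytest.raises(ValueError):
            fuse_pdfs(a, b)

    def test_gaussian_product_posterior_mean(self):
        axes = (np.linspace(-3, 7, 400), np.linspace(-5, 9, 400))
        m1, m2 = (1.0, 0.5), (3.0, 2.5)
        v1, v2 = (0.5, 1.2), (1.5, 0.8)
        fused = fuse_pdfs(
            discrete_gaussian(axes, m1, v1), discrete_gaussian(axes, m2, v2)
        )
        mean = pdf_expected_value(fused)
        for dim in range(2):
            expect = (m1[dim] / v1[dim] + m2[dim] / v2[dim]) / (
                1 / v1[dim] + 1 / v2[dim]
            )
            assert abs(mean[dim] - expect) <= fused.spacings[dim]

    def test_self_fusion_sharpens(self):
        axes = (np.linspace(-5, 5, 200), np.linspace(-5, 5, 200))
        p = discrete_gaussian(axes, (0.0, 0.0), (1.0, 2.0))
        assert effective_variance(fuse_pdfs(p, p)) <= effective_variance(p)


class TestSummaries:
    def test_expected_value_symmetric_and_point_mass(self):
        ax = np.linspace(-2, 2, 41)
        sym = PdfGrid((ax, ax), np.ones((41, 41))).normalize()
        np.testing.assert_allclose(pdf_expected_value(sym), [0.0, 0.0], atol=1e-12)
        vals = np.zeros((41, 41))
        vals[30, 10] = 1.0
        point = PdfGrid((ax, ax), vals).normalize()
        np.testing.assert_allclose(pdf_expected_value(point), [ax[30], ax[10]])

    def test_expected_value_requires_normalized(self):
        pdf = PdfGrid((np.linspace(0, 1, 5),), np.ones(5))
        with pytest.raises(ValueError):
            pdf_expected_value(pdf)

    def test_gaussian_mean_within_one_cell(self):
        axes = (np.linspace(-4, 6, 120), np.linspace(-6, 4, 90))
        pdf = discrete_gaussian(axes, (1.3, -0.7), (0.8, 1.1))
        mean = pdf_expected_value(pdf)
        assert abs(mean[0] - 1.3) <= pdf.spacings[0]
        assert abs(mean[1] + 0.7) <= pdf.spacings[1]

    def test_modes_unimodal_bimodal_and_tolerance(self):
        ax = np.linspace(0, 10, 101)
        uni = PdfGrid((ax,), np.exp(-0.5 * (ax - 4.0) ** 2)).normalize()
        assert pdf_modes(uni).shape == (1, 1)
        assert pdf_modes(uni)[0, 0] == pytest.approx(4.0, abs=0.1)
        two_equal = PdfGrid(
            (ax,), np.exp(-8 * (ax - 2) ** 2) + np.exp(-8 * (ax - 8) ** 2)
        ).normalize()
        assert len(pdf_modes(two_equal)) == 2
        lopsided = PdfGrid(
            (ax,), np.exp(-8 * (ax - 2) ** 2) + 0.9 * np.exp(-8 * (ax - 8) ** 2)
        ).normalize()
        assert len(pdf_modes(lopsided, rel_tol=0.05)) == 1
        assert pdf_modes(lopsided, rel_tol=0.05)[0, 0] == pytest.approx(2.0, abs=0.1)

    def test_flat_pdf_has_no_mode(self):
        flat = PdfGrid((np.linspace(0, 1, 10),), np.ones(10)).normalize()
        with pytest.raises(ValueError, match="no isolated mode"):
            pdf_modes(flat)

    def test_effective_variance_closed_form(self):
        a, b = 0.7, 2.3
        axes = (np.linspace(-6 * a, 6 * a, 300), np.linspace(-6 * b, 6 * b, 300))
        pdf = discrete_gaussian(axes, (0.0, 0.0), (a * a, b * b))
        assert effective_variance(pdf) == pytest.approx(np.log(a * a * b * b), abs=1e-3)

    def test_effective_variance_scaling_law(self):
        # rescaling both axes by k multiplies det(Sigma) by k^4
        k = 3.0
        axes = (np.linspace(-5, 5, 200), np.linspace(-5, 5, 200))
        pdf = discrete_gaussian(axes, (0.0, 0.0), (1.0, 0.5))
        scaled_axes = tuple(k * a for a in axes)
        scaled = PdfGrid(scaled_axes, pdf.values / (k * k), normalized=True)
        assert effective_variance(scaled) - effective_variance(pdf) == pytest.approx(
            4.0 * np.log(k), abs=1e-9
        )

    def test_effective_variance_degenerate(self):
        ax = np.linspace(0, 1, 11)
        vals = np.zeros((11, 11))
        vals[5, 5] = 1.0
        point = PdfGrid((ax, ax), vals).normalize()
        with pytest.raises(ValueError):
            effective_variance(point)
        assert effective_variance(point, on_degenerate="value") == -np.inf


def test_histogram_pdf_and_entropy(rng):
    samples = rng.normal(0.0, 1.0, 500)
    axis = np.linspace(-4, 4, 40)
    pdf = histogram_pdf(samples, axis)
    assert pdf.total_mass() == pytest.approx(1.0, abs=1e-9)
    wide = histogram_pdf(rng.uniform(-8, 8, 500), np.linspace(-8, 8, 40))
    assert pdf_entropy(wide) > pdf_entropy(pdf)


def test_build_output_grid_spans_and_pads():
    pts_a = np.array([[10.0, 100.0], [20.0, 200.0]])
    pts_b = np.array([[15.0, 50.0]])
    axes = build_output_grid(pts_a, pts_b, n_points=30)
    assert axes[0][0] < 10.0 and axes[0][-1] > 20.0
    assert axes[1][0] < 50.0 and axes[1][-1] > 200.0
    assert len(axes[0]) == len(axes[1]) == 30
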