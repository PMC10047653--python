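import numpy as np
import pytest
from scipy.stats import chi2_contingency, chisquare

from bhsic.bootstrap import (
    build_plan,
    draw_null_indices,
    draw_null_sample,
    weight_kernel,
)
from bhsic.statistic import CISample


class TestWeightKernel:
    def test_zero_delta_gives_one(self):
        assert weight_kernel(np.zeros(3), 2.0) == 1.0

    def test_delta_at_bandwidth_gives_e_minus_one(self):
        assert weight_kernel(np.array([2.0]), 4.0) == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("gamma", [0.0, -1.0, np.inf])
    def test_rejects_bad_gamma(self, gamma):
        with pytest.raises(ValueError):
            weight_kernel(np.ones(2), gamma)


class TestBuildPlan:
    def test_two_point_example(self):
        plan = build_plan(np.array([0.0, 1.0]), k_nn=2)
        # for z_0 = 0: candidates (self, other); gamma = 1; weights ~ (1, e^-1)
        assert plan.candidates[0].tolist() == [0, 1]
        assert plan.gamma[0] == pytest.approx(1.0)
        expect = np.array([1.0, np.exp(-1.0)])
        assert plan.weights[0] == pytest.approx(expect / expect.sum())

    def test_weights_normalised(self, rng):
        plan = build_plan(rng.standard_normal((40, 3)), k_nn=10)
        assert plan.weights.min() >= 0
        assert plan.weights.sum(axis=1) == pytest.approx(np.ones(40), abs=1e-12)
        assert np.all(plan.gamma > 0)

    def test_self_is_first_candidate(self, rng):
        plan = build_plan(rng.standard_normal((25, 2)), k_nn=5)
        assert np.array_equal(plan.candidates[:, 0], np.arange(25))

    def test_identical_z_gives_uniform_weights(self):
        with pytest.warns(RuntimeWarning):  # k_nn clamped to n
            plan = build_plan(np.zeros(4), k_nn=10)
        assert plan.weights == pytest.approx(np.full((4, 4), 0.25))

    def test_equidistant_candidates_share_weight(self):
        plan = build_plan(np.array([0.0, 1.0, -1.0]), k_nn=3)
        w = plan.weights[0]  # z=0 sees two candidates at distance 1
        assert w[1] == pytest.approx(w[2])

    def test_k_nn_clamped_with_warning(self, rng):
        with pytest.warns(RuntimeWarning):
            plan = build_plan(rng.standard_normal(5), k_nn=9)
        assert plan.k_nn == 5

    def test_tie_break_by_original_index(self):
        # duplicate z-values: stable order keeps lower indices first
        plan = build_plan(np.array([0.0, 1.0, 1.0, 1.0]), k_nn=2)
        assert plan.candidates[1].tolist() == [1, 2]


class TestDrawNullSample:
    def test_z_block_unchanged_bitwise(self, rng, small_sample):
        plan = build_plan(small_sample.z, k_nn=5)
        out = draw_null_sample(small_sample, plan, rng)
        assert np.array_equal(out.z, small_sample.z)

    def test_rows_come_from_observed_sample(self, rng, small_sample):
        plan = build_plan(small_sample.z, k_nn=5)
        out = draw_null_sample(small_sample, plan, rng)
        x_rows = {tuple(r) for r in small_sample.x}
        y_rows = {tuple(r) for r in small_sample.y}
        assert all(tuple(r) in x_rows for r in out.x)
        assert all(tuple(r) in y_rows for r in out.y)

    def test_k_nn_one_reproduces_the_sample(self, rng, small_sample):
        plan = build_plan(small_sample.z, k_nn=1)
        out = draw_null_sample(small_sample, plan, rng)
        assert np.array_equal(out.x, small_sample.x)
        assert np.array_equal(out.y, small_sample.y)

    def test_plan_size_mismatch_rejected(self, rng, small_sample):
        plan = build_plan(small_sample.z[:10], k_nn=3)
        with pytest.raises(ValueError):
            draw_null_sample(small_sample, plan, rng)

    def test_marginal_matches_weights(self, rng):
        """Chi-square goodness of fit of the index draws against the weights."""
        z = rng.standard_normal((12, 1))
        plan = build_plan(z, k_nn=4)
        draws = 10_000
        counts = np.zeros(plan.k_nn)
        for _ in range(draws):
            ix, _ = draw_null_indices(plan, rng)
            pos = np.flatnonzero(plan.candidates[0] == ix[0])[0]
            counts[pos] += 1
        stat = chisquare(counts, plan.weights[0] * draws)
        assert stat.pvalue > 0.001

    def test_x_and_y_draws_independent(self, rng):
        """The (x index, y index) joint factorises: chi-square on the table."""
        z = rng.standard_normal((10, 1))
        plan = build_plan(z, k_nn=3)
        draws = 10_000
        table = np.zeros((plan.k_nn, plan.k_nn))
        for _ in range(draws):
            ix, iy = draw_null_indices(plan, rng)
            px = np.flatnonzero(plan.candidates[0] == ix[0])[0]
            py = np.flatnonzero(plan.candidates[0] == iy[0])[0]
            table[px, py] += 1
        assert chi2_contingency(table).pvalue > 0.001


class TestConditionalConsistency:
    def test_weighted_conditional_mean_converges(self):
        """Nadaraya-Watson-style weights localise as n grows: the smoothing
        bias of the weighted conditional mean shrinks with the neighbourhood
        radius.  (With k_nn fixed the noise-averaging variance does not
        shrink, so the bias is measured on a noise-free response.)"""
        errors = []
        for n in (100, 400, 1600):
            rng = np.random.default_rng(n)
            z = rng.uniform(-2, 2, size=n)
            x = np.tanh(z)
            plan = build_plan(z, k_nn=10)
            fitted = np.array(
                [plan.weights[i] @ x[plan.candidates[i]] for i in range(n)]
            )
            errors.append(np.abs(fitted - np.tanh(z)).mean())
        assert errors[0] > errors[1] > errors[2]
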