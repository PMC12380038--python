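import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import betaln

from propp.data import SubjectTable
from propp.power_prior import (
    PriorSpec,
    WeightedCounts,
    effective_external_weight,
    log_marginal_delta,
    log_scaling_constant,
    sample_delta,
    sample_theta_given_delta,
    weighted_counts,
)

from _oracles import joint_posterior_moments, marginal_delta_density


class TestWeightedCounts:
    def test_direct_sums(self):
        import pandas as pd

        tab = SubjectTable(pd.DataFrame({"z": [1, 1, 1, 0], "y": [1, 0, 1, 1]}))
        c = weighted_counts(tab, np.array([1.0, 1.0, 1.0, 0.5]))
        assert (c.a_0, c.b_0, c.a_e, c.b_e) == (2.0, 1.0, 0.5, 0.0)

    def test_zero_external_weights(self, vemurafenib_counts):
        w = np.where(vemurafenib_counts.z == 1, 1.0, 0.0)
        c = weighted_counts(vemurafenib_counts, w)
        assert c.a_e == c.b_e == 0.0

    def test_published_case_counts_at_unit_weight(self, vemurafenib_counts):
        c = weighted_counts(vemurafenib_counts, np.ones(vemurafenib_counts.n))
        assert (c.a_0, c.b_0, c.a_e, c.b_e) == (75.0, 57.0, 129.0, 112.0)

    def test_negative_weight_rejected(self, vemurafenib_counts):
        w = np.ones(vemurafenib_counts.n)
        w[0] = -0.1
        with pytest.raises(ValueError):
            weighted_counts(vemurafenib_counts, w)


class TestScalingConstant:
    def test_delta_zero_is_log_one(self, toy_counts):
        assert log_scaling_constant(0.0, toy_counts) == pytest.approx(0.0)

    def test_delta_one_unit_counts(self):
        c = WeightedCounts(a_e=1.0, b_e=1.0, a_0=0.0, b_0=0.0)
        assert log_scaling_constant(1.0, c) == pytest.approx(np.log(1 / 6))

    def test_matches_quadrature_at_case_counts(self):
        c = WeightedCounts(a_e=129.0, b_e=112.0, a_0=0.0, b_0=0.0)
        d = 0.5
        val, _ = quad(lambda t: t ** (d * c.a_e) * (1 - t) ** (d * c.b_e), 0, 1)
        assert log_scaling_constant(d, c) == pytest.approx(np.log(val), rel=1e-8)

    def test_closed_form_under_weight_scaling(self):
        # scaling all external weights by c rescales the sufficient statistics;
        # the constant must track its closed form, not any cached value
        base = WeightedCounts(a_e=40.0, b_e=30.0, a_0=10.0, b_0=10.0)
        for scale in (1.0, 0.5, 0.1):
            c = WeightedCounts(base.a_e * scale, base.b_e * scale, base.a_0, base.b_0)
            for d in (0.2, 0.9):
                expected = betaln(d * c.a_e + 1, d * c.b_e + 1)
                assert log_scaling_constant(d, c) == pytest.approx(expected)


class TestMarginalDelta:
    def test_no_external_information_returns_prior(self):
        c = WeightedCounts(0.0, 0.0, 5.0, 3.0)
        grid = np.linspace(0, 1, 7)
        vals = log_marginal_delta(grid, c) - log_marginal_delta(0.0, c)
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_agrees_with_theta_quadrature(self, toy_counts):
        grid = np.linspace(0.0, 1.0, 21)
        ours = log_marginal_delta(grid, toy_counts)
        oracle = marginal_delta_density(toy_counts, grid)
        # densities agree up to an additive constant
        diff = ours - oracle
        assert np.ptp(diff) < 1e-6

    def test_uniform_prior_is_pure_beta_ratio(self, toy_counts):
        d = 0.37
        expected = betaln(
            d * toy_counts.a_e + toy_counts.a_0 + 1.0, d * toy_counts.b_e + toy_counts.b_0 + 1.0
        ) - betaln(d * toy_counts.a_e + 1.0, d * toy_counts.b_e + 1.0)
        assert log_marginal_delta(d, toy_counts) == pytest.approx(expected)


class TestSampler:
    def test_prior_recovery_without_external_data(self):
        c = WeightedCounts(0.0, 0.0, 10.0, 5.0)
        draws, acc = sample_delta(c, seed=0, n_proposals=20_000)
        assert acc == 1.0
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_matches_quadrature_oracle(self, toy_counts):
        e_d, _, _ = joint_posterior_moments(toy_counts)
        draws, _ = sample_delta(toy_counts, seed=1, n_proposals=20_000, min_draws=10_000)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - e_d) < 3 * se

    def test_conflict_pushes_delta_toward_zero(self):
        conflict = WeightedCounts(a_e=10.0, b_e=90.0, a_0=90.0, b_0=10.0)
        draws, _ = sample_delta(conflict, seed=2, n_proposals=20_000, min_draws=5_000)
        assert draws.mean() < 0.25  # far below the no-information mean of 0.5

    def test_non_uniform_prior_shifts_posterior(self):
        c = WeightedCounts(5.0, 5.0, 5.0, 5.0)
        lo, _ = sample_delta(c, PriorSpec(1.0, 4.0), seed=3, min_draws=5_000)
        hi, _ = sample_delta(c, PriorSpec(4.0, 1.0), seed=3, min_draws=5_000)
        assert lo.mean() < hi.mean()

    def test_reproducible_given_seed(self, toy_counts):
        a, _ = sample_delta(toy_counts, seed=42)
        b, _ = sample_delta(toy_counts, seed=42)
        np.testing.assert_array_equal(a, b)


class TestConditionalTheta:
    def test_trial_only_posterior_at_delta_zero(self):
        c = WeightedCounts(a_e=129.0, b_e=112.0, a_0=75.0, b_0=57.0)
        draws = sample_theta_given_delta(np.zeros(40_000), c, seed=0)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 76 / 134) < 3 * se

    def test_pooling_at_delta_one(self):
        c = WeightedCounts(a_e=129.0, b_e=112.0, a_0=75.0, b_0=57.0)
        draws = sample_theta_given_delta(np.ones(40_000), c, seed=0)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 205 / 375) < 3 * se

    def test_symmetric_counts_centred_at_half(self):
        c = WeightedCounts(a_e=2.0, b_e=2.0, a_0=1.0, b_0=1.0)
        draws = sample_theta_given_delta(np.full(40_000, 0.5), c, seed=1)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se


def test_effective_external_weight_arithmetic():
    assert effective_external_weight(np.ones(400), np.full(100, 0.5)) == pytest.approx(200.0)
    assert effective_external_weight(np.zeros(50), np.full(100, 0.7)) == 0.0
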