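import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from propp.data import SubjectTable
from propp.propensity import (
    PropensityError,
    PropensityFit,
    WeightScheme,
    balance_summary,
    compute_weights,
    fit_propensity,
)


def _fit_with_lambda(lam, n_trial):
    """Minimal PropensityFit carrying given fitted probabilities."""
    lam = np.asarray(lam, dtype=float)
    return PropensityFit(
        coefficients=pd.Series(dtype=float),
        lambda_=lam,
        converged=True,
        separation_flags=(lam <= 1e-8) | (lam >= 1 - 1e-8),
        encoding=None,
        deviance=np.nan,
        n_trial=n_trial,
        n=len(lam),
    )


class TestFit:
    def test_no_signal_lambda_near_half_and_balance_identities(self, no_signal_table):
        fit = fit_propensity(no_signal_table)
        n0, n = no_signal_table.n_trial, no_signal_table.n
        assert fit.converged
        assert np.allclose(fit.lambda_.mean(), n0 / n, atol=1e-8)
        assert np.allclose(fit.lambda_.sum(), n0, atol=1e-6)
        # no covariate signal: every lambda close to the marginal 1/2
        assert np.all(np.abs(fit.lambda_ - 0.5) < 0.2)

    def test_sum_lambda_equals_n_trial_with_signal(self):
        rng = np.random.default_rng(5)
        n0, ne = 300, 500
        z = np.r_[np.ones(n0, dtype=int), np.zeros(ne, dtype=int)]
        x = rng.normal(size=(n0 + ne, 2)) + 0.5 * z[:, None]
        y = rng.binomial(1, 0.5, n0 + ne)
        fit = fit_propensity(SubjectTable.from_arrays(z, y, x))
        assert np.allclose(fit.lambda_.sum(), n0, atol=1e-6)

    def test_external_only_level_separates_to_zero(self):
        rng = np.random.default_rng(1)
        n0 = ne = 100
        z = np.r_[np.ones(n0, dtype=int), np.zeros(ne, dtype=int)]
        group = np.array(["a"] * n0 + ["a"] * 70 + ["b"] * 30)
        df = pd.DataFrame({"z": z, "y": rng.binomial(1, 0.5, n0 + ne), "group": group})
        with pytest.warns(UserWarning, match="quasi-separation"):
            fit = fit_propensity(SubjectTable(df))
        b_mask = group == "b"
        assert np.all(fit.lambda_[b_mask] < 1e-8)
        assert fit.separation_flags[b_mask].all()
        tab = SubjectTable(df)
        w = compute_weights(fit, tab, "att_trial")
        assert np.all(w[b_mask] < 1e-6)

    def test_one_source_only_is_an_error(self):
        df = pd.DataFrame({"z": [1, 1, 1], "y": [0, 1, 0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(PropensityError, match="no contrast"):
            fit_propensity(SubjectTable(df))


class TestWeights:
    @pytest.mark.parametrize(
        "lam_ext, expected",
        [(0.5, 1.0), (0.75, 1.0), (0.2, 0.25)],
        ids=["odds-one", "capped", "below-cap"],
    )
    def test_att_trial_external_weights(self, lam_ext, expected):
        tab = SubjectTable(pd.DataFrame({"z": [1, 0], "y": [1, 0]}))
        fit = _fit_with_lambda([0.9, lam_ext], n_trial=1)
        w = compute_weights(fit, tab, "att_trial")
        assert w[0] == 1.0
        assert w[1] == pytest.approx(expected)

    def test_att_trial_handles_lambda_one_without_error(self):
        tab = SubjectTable(pd.DataFrame({"z": [1, 0], "y": [1, 0]}))
        fit = _fit_with_lambda([0.9, 1.0], n_trial=1)
        w = compute_weights(fit, tab, "att_trial")
        assert w[1] == 1.0

    def test_ate_non_overlap_is_an_error(self):
        tab = SubjectTable(pd.DataFrame({"z": [1, 0], "y": [1, 0]}))
        fit = _fit_with_lambda([0.0, 0.5], n_trial=1)
        with pytest.raises(PropensityError, match="non-overlap"):
            compute_weights(fit, tab, WeightScheme("ate", cap_at_one=False))

    def test_att_external_scheme(self):
        tab = SubjectTable(pd.DataFrame({"z": [1, 0], "y": [1, 0]}))
        fit = _fit_with_lambda([0.8, 0.3], n_trial=1)
        w = compute_weights(fit, tab, WeightScheme("att_external", cap_at_one=False))
        assert w[0] == pytest.approx(0.2 / 0.8)
        assert w[1] == 1.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown weighting scheme"):
            WeightScheme("matching")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_att_trial_weights_bounded_and_permutation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        z = np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)]
        x = rng.normal(size=(n, 2)) + 0.3 * z[:, None]
        tab = SubjectTable.from_arrays(z, rng.binomial(1, 0.5, n), x)
        fit = fit_propensity(tab)
        w = compute_weights(fit, tab, "att_trial")
        assert np.all((w >= 0) & (w <= 1))
        perm = rng.permutation(n)
        tab_p = SubjectTable(tab.df.iloc[perm].drop(columns="subject_id"), covariates=tab.covariates)
        fit_p = fit_propensity(tab_p)
        w_p = compute_weights(fit_p, tab_p, "att_trial")
        np.testing.assert_allclose(fit_p.lambda_, fit.lambda_[perm], atol=1e-6)
        np.testing.assert_allclose(w_p, w[perm], atol=1e-6)

    def test_external_weight_sum_approaches_n_trial_under_identical_laws(self):
        # identical covariate laws, Ne >> N0: total external weight ~ N0
        rng = np.random.default_rng(3)
        n0, ne = 400, 2000
        z = np.r_[np.ones(n0, dtype=int), np.zeros(ne, dtype=int)]
        x = rng.normal(size=(n0 + ne, 3))
        tab = SubjectTable.from_arrays(z, rng.binomial(1, 0.5, n0 + ne), x)
        fit = fit_propensity(tab)
        w = compute_weights(fit, tab, "att_trial")
        ext_sum = w[tab.z == 0].sum()
        assert ext_sum == pytest.approx(n0, rel=0.05)


class TestBalance:
    def test_identical_distributions_have_small_smd(self, no_signal_table):
        fit = fit_propensity(no_signal_table)
        w = compute_weights(fit, no_signal_table, "att_trial")
        tab = balance_summary(no_signal_table, w)
        assert (tab["smd_raw"].abs() < 0.2).all()
        assert (tab["smd_weighted"].abs() < 0.2).all()

    def test_weighting_shrinks_a_real_shift(self):
        rng = np.random.default_rng(9)
        n0, ne = 400, 400
        z = np.r_[np.ones(n0, dtype=int), np.zeros(ne, dtype=int)]
        x = rng.normal(size=(n0 + ne, 1))
        x[z == 0] += 1.0  # external mean shifted by +1 SD
        tab = SubjectTable.from_arrays(z, rng.binomial(1, 0.5, n0 + ne), x)
        fit = fit_propensity(tab)
        w = compute_weights(fit, tab, "att_trial")
        bal = balance_summary(tab, w)
        assert abs(bal.loc[0, "smd_weighted"]) < abs(bal.loc[0, "smd_raw"])

    def test_zero_external_weight_reports_undefined(self, no_signal_table):
        w = np.where(no_signal_table.z == 1, 1.0, 0.0)
        bal = balance_summary(no_signal_table, w)
        assert bal["smd_weighted"].isna().all() or (bal["smd_weighted"] is None)
        assert np.isfinite(bal["smd_raw"]).all()

    def test_negative_weights_rejected(self, no_signal_table):
        with pytest.raises(ValueError):
            balance_summary(no_signal_table, -np.ones(no_signal_table.n))
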