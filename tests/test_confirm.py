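"""Confirmatory state-space fits, elimination, BIC, two-stage iteration."""

import numpy as np
import pandas as pd
import pytest

from esmlag import (
    FitError,
    LagKernel,
    SimulationConfig,
    build_lag_design,
    fit_lag_model,
    iterate_two_stage,
    latent_observed_panel,
    simulate_panel,
    summed_effect,
)
from esmlag.confirm import LagModelFit


def _ols_with_dummies(design, lags):
    wide = design.wide.dropna(subset=[f"x_lag{l}" for l in lags] + ["y"])
    X = wide[[f"x_lag{l}" for l in lags]].to_numpy()
    y = wide["y"].to_numpy()
    codes, uniq = pd.factorize(wide["subject_id"])
    D = np.zeros((len(y), len(uniq)))
    D[np.arange(len(y)), codes] = 1.0
    XX = np.hstack([X, D])
    beta = np.linalg.lstsq(XX, y, rcond=None)[0]
    resid = y - XX @ beta
    n = len(y)
    s2 = resid @ resid / n
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    return beta[: len(lags)], loglik, n


class TestOracleEquivalence:
    def test_ml_matches_ols_with_subject_dummies(self, complete_panel):
        sp, _ = complete_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 3)
        fit = fit_lag_model(design, (1, 2, 3), eliminate=False)
        beta_ols, ll_ols, n = _ols_with_dummies(design, (1, 2, 3))
        np.testing.assert_allclose(fit.cross["beta"], beta_ols, atol=1e-6)
        assert fit.loglik == pytest.approx(ll_ols, abs=1e-6)
        assert fit.n_obs == n

    def test_bic_identity(self, complete_panel):
        sp, _ = complete_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 3)
        fit = fit_lag_model(design, (1, 2), eliminate=False)
        k = len(fit.cross) + len(fit.auto) + fit.n_subjects + 1
        assert fit.n_params == k
        assert fit.bic == pytest.approx(
            -2.0 * fit.loglik + k * np.log(fit.n_obs), abs=1e-10
        )


class TestSummedEffect:
    def _fit(self, betas):
        cross = pd.DataFrame(
            {"lag": range(1, len(betas) + 1), "beta": betas,
             "se": 0.01, "z": 1.0, "p": 0.001}
        )
        empty = pd.DataFrame(columns=["lag", "beta", "se", "z", "p"])
        return LagModelFit("x", "y", cross, empty, -10.0, 20.0, 100, 5, 1.0, 0.05, 3)

    def test_sum_of_retained_betas(self):
        fit = self._fit([-0.10, -0.05, -0.02])
        assert summed_effect(fit) == pytest.approx(-0.17, abs=1e-12)
        assert summed_effect(fit) == fit.cross["beta"].sum()

    def test_empty_set_gives_zero_and_ns(self):
        fit = self._fit([])
        assert summed_effect(fit) == 0.0
        assert not fit.significant
        assert str(fit.cross_lags) == "n.s."

    def test_single_beta(self):
        assert summed_effect(self._fit([0.3])) == pytest.approx(0.3)


class TestRecovery:
    def test_mcar_recovery_of_true_lags(self, recovery_panel):
        sp, _ = recovery_panel
        final = iterate_two_stage(sp, "sleep_quality", "psychosis")
        retained = set(final.fit.cross_lags.lags)
        assert {1, 2, 3, 4, 5} <= retained
        est = {int(r.lag): r.beta for r in final.fit.cross.itertuples()}
        for l in range(1, 6):
            assert est[l] == pytest.approx(-0.3, abs=0.05)
        assert final.converged
        assert final.trace  # iteration trace recorded

    def test_elimination_drops_null_candidates(self, recovery_panel):
        sp, _ = recovery_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 20)
        fit = fit_lag_model(design, (1, 2, 3, 4, 5, 15, 20))
        assert set(fit.cross["lag"]) == {1, 2, 3, 4, 5}
        assert ("sleep_quality", 15) in fit.dropped
        assert ("sleep_quality", 20) in fit.dropped

    def test_ar1_autoregression_recovery(self):
        kern = LagKernel({("psychosis", "psychosis"): [0.5]})
        cfg = SimulationConfig(
            seed=3, kernels=kern, n_subjects=30, n_days=300, missing_rate=0.31
        )
        sp = latent_observed_panel(simulate_panel(cfg), cfg)
        final = iterate_two_stage(sp, "psychosis", "psychosis")
        assert final.fit.cross_lags.lags == (1,)
        assert final.fit.cross["beta"].iloc[0] == pytest.approx(0.5, abs=0.05)
        assert final.n_cycles <= 3

    def test_pure_noise_pair_reports_ns(self):
        cfg = SimulationConfig(
            seed=5, kernels=LagKernel({}), n_subjects=30, n_days=300,
            missing_rate=0.31,
        )
        sp = latent_observed_panel(simulate_panel(cfg), cfg)
        final = iterate_two_stage(sp, "sleep_quality", "psychosis")
        assert final.fit.cross_lags.lags == ()
        assert summed_effect(final.fit) == 0.0
        assert final.converged

    def test_two_stage_deterministic(self, recovery_panel):
        sp, _ = recovery_panel
        a = iterate_two_stage(sp, "sleep_quality", "psychosis")
        b = iterate_two_stage(sp, "sleep_quality", "psychosis")
        pd.testing.assert_frame_equal(a.fit.cross, b.fit.cross)
        assert a.fit.loglik == b.fit.loglik


class TestErrors:
    def test_empty_candidate_set_rejected(self, complete_panel):
        sp, _ = complete_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 3)
        with pytest.raises(FitError, match="empty"):
            fit_lag_model(design, ())

    def test_subjects_shorter_than_window_rejected(self):
        from types import SimpleNamespace

        df = pd.DataFrame(
            {
                "subject_id": "P1",
                "date": pd.date_range("2020-01-01", periods=5),
                "x": np.random.default_rng(0).normal(size=5),
                "y": np.random.default_rng(1).normal(size=5),
            }
        )
        design = build_lag_design(SimpleNamespace(data=df), "x", "y", max_lag=4)
        with pytest.raises(FitError, match="no usable rows"):
            fit_lag_model(design, (4,), condition_lag=4)
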