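"""Exploratory penalized varying-coefficient screen."""

import numpy as np
import pandas as pd
import pytest

from esmlag import (
    FitError,
    build_lag_design,
    fit_smooth_lag,
    select_lags,
)
from esmlag.explore import SmoothLagFit, bspline_basis, difference_penalty


def _fit_from_pvalues(pvals):
    L = len(pvals)
    table = pd.DataFrame(
        {"lag": np.arange(1, L + 1), "beta": 0.1, "se": 0.1, "z": 1.0, "p": pvals}
    )
    return SmoothLagFit(table, k=L, lam=1.0, tau=0.0, edf=3.0, n=100,
                        subject_intercept_var=0.0, gcv=1.0)


class TestSelectLags:
    def test_all_nonsignificant_gives_empty_set(self):
        assert select_lags(_fit_from_pvalues([1.0] * 10), 0.05).lags == ()

    def test_run_notation_of_selected_lags(self):
        pv = [1.0] * 10
        for l in (1, 2, 3, 5, 6):
            pv[l - 1] = 0.001
        assert str(select_lags(_fit_from_pvalues(pv), 0.05)) == "1-3 and 5-6"

    def test_alpha_one_selects_every_lag(self):
        ls = select_lags(_fit_from_pvalues([0.5] * 8), alpha=1.0)
        assert ls.lags == tuple(range(1, 9))


class TestSmoothFit:
    def test_unpenalized_full_basis_matches_per_lag_regression(self, complete_panel):
        # k = L, lambda = 0, no intercepts: the stacked spline fit spans the
        # same space as separate per-lag regressions on complete data
        sp, _ = complete_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 20)
        fit = fit_smooth_lag(design, k=20, lam=0.0, intercepts="none")
        for l in range(1, 21):
            sub = design.long[design.long["lag"] == l]
            x, y = sub["x"].to_numpy(), sub["y"].to_numpy()
            assert fit.table.loc[l - 1, "beta"] == pytest.approx(
                (x @ y) / (x @ x), abs=1e-6
            )

    def test_heavy_first_order_penalty_tends_to_pooled_slope(self, complete_panel):
        # first-difference penalty nullspace = constants, so lambda -> inf
        # shrinks beta(l) to the pooled stacked OLS slope
        sp, _ = complete_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 20)
        fit = fit_smooth_lag(
            design, k=19, lam=1e10, penalty_order=1, intercepts="none"
        )
        x = design.long["x"].to_numpy()
        y = design.long["y"].to_numpy()
        pooled = (x @ y) / (x @ x)
        np.testing.assert_allclose(fit.table["beta"], pooled, atol=1e-4)

    def test_scale_equivariance_unpenalized(self, complete_panel):
        sp, _ = complete_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 10)
        base = fit_smooth_lag(design, k=10, lam=0.0, intercepts="none")
        scaled = design.long.copy()
        scaled["x"] = scaled["x"] * 4.0
        from types import SimpleNamespace

        d2 = SimpleNamespace(
            long=scaled, max_lag=10, pair_counts=design.pair_counts
        )
        fit2 = fit_smooth_lag(d2, k=10, lam=0.0, intercepts="none")
        np.testing.assert_allclose(
            fit2.table["beta"], base.table["beta"] / 4.0, atol=1e-8
        )

    def test_recovery_flags_true_lags(self, recovery_panel):
        sp, _ = recovery_panel
        design = build_lag_design(sp, "sleep_quality", "psychosis", 20)
        fit = fit_smooth_lag(design)
        flagged = set(select_lags(fit, 0.05).lags)
        assert {1, 2, 3, 4, 5} <= flagged
        assert fit.table["se"].gt(0).all()
        assert fit.table["p"].between(0, 1).all()

    def test_too_few_distinct_lags_rejected(self):
        from types import SimpleNamespace

        long = pd.DataFrame(
            {
                "subject_id": "P1",
                "date": pd.date_range("2020-01-01", periods=6),
                "lag": [1, 1, 2, 2, 3, 3],
                "y": np.random.default_rng(0).normal(size=6),
                "x": np.random.default_rng(1).normal(size=6),
            }
        )
        design = SimpleNamespace(long=long, max_lag=3, pair_counts=pd.Series([2, 2, 2], index=[1, 2, 3]))
        with pytest.raises(FitError, match="distinct lags"):
            fit_smooth_lag(design, k=4)


class TestBasis:
    def test_partition_of_unity(self):
        B = bspline_basis(np.arange(1, 21), 19, 20)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_difference_penalty_nullspace(self):
        S1 = difference_penalty(6, order=1)
        S2 = difference_penalty(6, order=2)
        const = np.ones(6)
        lin = np.arange(6.0)
        assert const @ S1 @ const == pytest.approx(0.0)
        assert const @ S2 @ const == pytest.approx(0.0)
        assert lin @ S2 @ lin == pytest.approx(0.0)
        assert lin @ S1 @ lin > 0
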