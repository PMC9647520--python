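"""Synthetic diary generator: dynamics, discretization, missingness."""

import numpy as np
import pandas as pd
import pytest

from esmlag import (
    LagKernel,
    SimulationConfig,
    SimulationError,
    apply_missingness,
    discretize_to_likert,
    latent_observed_panel,
    simulate_panel,
    spectral_radius,
)
from esmlag.synth import LATENT_VARIABLES, TruePanel, _likert


def _ar1_config(seed=7, phi=0.5, **kw):
    kern = LagKernel({("psychosis", "psychosis"): [phi]})
    defaults = dict(
        seed=seed, kernels=kern, n_subjects=30, n_days=300, max_lag=1,
        subject_intercept_sd=0.0, missing_rate=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestLatentDynamics:
    def test_degenerate_config_gives_constant_zero(self):
        cfg = SimulationConfig(
            seed=1, n_subjects=3, n_days=20, max_lag=2,
            innovation_sd={v: 0.0 for v in LATENT_VARIABLES},
            subject_intercept_sd=0.0, missing_rate=0.0,
        )
        tp = simulate_panel(cfg)
        assert np.all(tp.latent[LATENT_VARIABLES].to_numpy() == 0.0)

    def test_ar1_lag1_autocorrelation_recovered(self):
        # closed form: AR(1) with coefficient phi has lag-1 autocorrelation phi
        cfg = _ar1_config()
        tp = simulate_panel(cfg)
        acs = []
        for _, g in tp.latent.groupby("subject_id"):
            v = g["psychosis"].to_numpy()
            acs.append(np.corrcoef(v[1:], v[:-1])[0, 1])
        assert abs(np.mean(acs) - 0.5) < 0.05

    def test_unit_variance_calibration(self):
        cfg = _ar1_config()
        tp = simulate_panel(cfg)
        assert abs(tp.latent["psychosis"].var() - 1.0) < 0.1
        assert abs(tp.latent["sleep_quality"].var() - 1.0) < 0.1

    def test_same_seed_bit_identical(self):
        cfg = _ar1_config(missing_rate=0.3)
        a, b = simulate_panel(cfg), simulate_panel(cfg)
        pd.testing.assert_frame_equal(a.latent, b.latent)
        da = discretize_to_likert(a, cfg)
        db = discretize_to_likert(b, cfg)
        pd.testing.assert_frame_equal(da.diary, db.diary)
        pd.testing.assert_frame_equal(
            apply_missingness(da, cfg).data, apply_missingness(db, cfg).data
        )

    def test_stationarity_guard_rejects_explosive_kernel(self):
        with pytest.raises(SimulationError, match="non-stationary"):
            SimulationConfig(
                seed=1, kernels=LagKernel({("psychosis", "psychosis"): [0.7, 0.4]})
            )

    def test_kernel_validation(self):
        with pytest.raises(SimulationError, match=r"\|beta\| >= 1"):
            LagKernel({("psychosis", "psychosis"): [1.2]})
        with pytest.raises(SimulationError, match="unknown variable"):
            LagKernel({("nonsense", "psychosis"): [0.1]})

    def test_variance_stable_over_long_run(self):
        # final-third vs middle-third variance ratio within [0.5, 2]
        cfg = _ar1_config(n_subjects=5, n_days=600)
        x = simulate_panel(cfg).latent["psychosis"].to_numpy().reshape(5, 600)
        v_mid = x[:, 200:400].var()
        v_end = x[:, 400:].var()
        assert 0.5 < v_end / v_mid < 2.0

    def test_spectral_radius_of_empty_kernel_is_zero(self):
        assert spectral_radius(LagKernel({}), 3) == pytest.approx(0.0)


class TestDiscretization:
    def test_centre_maps_to_middle_level(self):
        z = np.array([-2.0, 0.0, 2.0])
        assert _likert(z, 7)[1] == 4
        assert _likert(np.array([0.0]), 5)[0] == 3

    def test_extreme_latent_clamps_to_top_level(self):
        assert _likert(np.array([10.0]), 5)[0] == 5
        assert _likert(np.array([-10.0]), 7)[0] == 1

    def test_duration_identity_at_centre_and_quarter_grid(self):
        cfg = SimulationConfig(
            seed=2, n_subjects=2, n_days=30, max_lag=2,
            duration_mean_hours=7.5, duration_sd_hours=1.0, missing_rate=0.0,
        )
        tp = simulate_panel(cfg)
        tp.latent.loc[tp.latent.index[0], "sleep_duration"] = 0.0
        diary = discretize_to_likert(tp, cfg).diary
        assert diary["sleep_duration"].iloc[0] == 7.5
        assert np.all(diary["sleep_duration"] * 4 == np.round(diary["sleep_duration"] * 4))
        assert diary["sleep_duration"].between(0, 16).all()

    def test_likert_ranges(self):
        cfg = SimulationConfig(seed=3, n_subjects=3, n_days=50, max_lag=2, missing_rate=0.0)
        diary = discretize_to_likert(simulate_panel(cfg), cfg).diary
        assert diary["sleep_quality"].between(1, 5).all()
        assert diary["suspicious"].between(1, 7).all()


class TestMissingness:
    def test_zero_rate_keeps_every_day(self):
        cfg = SimulationConfig(seed=4, n_subjects=3, n_days=40, max_lag=2, missing_rate=0.0)
        tp = discretize_to_likert(simulate_panel(cfg), cfg)
        assert len(apply_missingness(tp, cfg).data) == 3 * 40

    def test_mcar_rate_within_three_binomial_sd(self):
        cfg = SimulationConfig(
            seed=5, n_subjects=30, n_days=340, max_lag=2, missing_rate=0.31
        )
        tp = discretize_to_likert(simulate_panel(cfg), cfg)
        n = 30 * 340
        frac = len(apply_missingness(tp, cfg).data) / n
        sd = np.sqrt(0.31 * 0.69 / n)
        assert abs(frac - 0.69) < 3 * sd

    def test_symptom_dependent_mode_selects_low_symptom_days(self):
        cfg = SimulationConfig(
            seed=6, n_subjects=30, n_days=340, max_lag=2,
            missing_rate=0.31, missingness_mode="symptom", missing_slope=1.0,
            kernels=LagKernel({("psychosis", "psychosis"): [0.4]}),
        )
        tp = simulate_panel(cfg)
        sp = latent_observed_panel(tp, cfg)
        observed_mean = (
            sp.data.set_index(["subject_id", "date"])["psychosis_raw"].mean()
        )
        assert observed_mean < tp.latent["psychosis"].mean()
        # marginal rate still calibrated
        frac = len(sp.data) / len(tp.latent)
        assert abs(frac - 0.69) < 3 * np.sqrt(0.31 * 0.69 / len(tp.latent))

    def test_invalid_missing_rate_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(seed=1, missing_rate=1.0)

    def test_missingness_requires_discretized_diary(self):
        cfg = SimulationConfig(seed=1, n_subjects=2, n_days=20, max_lag=2)
        tp = simulate_panel(cfg)
        with pytest.raises(SimulationError, match="discretize"):
            apply_missingness(tp, cfg)

    def test_observed_is_subset_of_latent_days(self):
        cfg = SimulationConfig(seed=8, n_subjects=4, n_days=60, max_lag=2, missing_rate=0.4)
        tp = discretize_to_likert(simulate_panel(cfg), cfg)
        obs = apply_missingness(tp, cfg).data
        latent_keys = set(zip(tp.latent["subject_id"], tp.latent["date"]))
        assert set(zip(obs["subject_id"], obs["date"])) <= latent_keys
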