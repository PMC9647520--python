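"""Shared fixtures: small synthetic panels generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from esmlag import (
    DiaryPanel,
    LagKernel,
    SimulationConfig,
    latent_observed_panel,
    simulate_panel,
)
from esmlag.items import SYMPTOM_ITEMS


@pytest.fixture(scope="session")
def recovery_panel():
    """30 subjects x 300 days, 31% MCAR, true kernel beta(1..5) = -0.3 on
    sleep_quality -> psychosis; person-standardized latent series."""
    kern = LagKernel({("sleep_quality", "psychosis"): [-0.3] * 5})
    cfg = SimulationConfig(
        seed=11, kernels=kern, n_subjects=30, n_days=300, missing_rate=0.31
    )
    return latent_observed_panel(simulate_panel(cfg), cfg), cfg


@pytest.fixture(scope="session")
def complete_panel():
    """8 subjects x 120 days, no missingness, kernel beta = (-0.3, -0.2)."""
    kern = LagKernel({("sleep_quality", "psychosis"): [-0.3, -0.2]})
    cfg = SimulationConfig(
        seed=42, kernels=kern, n_subjects=8, n_days=120, missing_rate=0.0
    )
    return latent_observed_panel(simulate_panel(cfg), cfg), cfg


def make_diary_frame(
    n_subjects: int = 2, n_days: int = 40, seed: int = 0
) -> pd.DataFrame:
    """Raw diary rows with valid in-range values."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        dates = pd.date_range("2020-01-01", periods=n_days, freq="D")
        for d in dates:
            row = {
                "subject_id": f"P{s + 1}",
                "date": d.strftime("%Y-%m-%d"),
                "sleep_duration": float(rng.integers(16, 40)) * 0.25,
                "sleep_quality": int(rng.integers(1, 6)),
            }
            for item in SYMPTOM_ITEMS:
                row[item] = int(rng.integers(1, 8))
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def diary_frame() -> pd.DataFrame:
    return make_diary_frame()


@pytest.fixture
def diary_panel(diary_frame) -> DiaryPanel:
    return DiaryPanel(diary_frame)
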