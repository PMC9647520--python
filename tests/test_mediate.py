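"""Lag-space mediation: verdicts, accounting identity, model comparison."""

import numpy as np
import pytest

from esmlag import (
    FitError,
    LagKernel,
    SimulationConfig,
    compare_mediation,
    fit_mediated_model,
    fit_path_a,
    latent_observed_panel,
    path_diagram,
    run_mediation,
    simulate_panel,
)
from esmlag.mediate import MediationResult


@pytest.fixture(scope="module")
def full_mediation_panel():
    """sleep_duration -> negative_affect -> psychosis with no direct path."""
    kern = LagKernel(
        {
            ("sleep_duration", "negative_affect"): [-0.3] * 3,
            ("negative_affect", "psychosis"): [0.3] * 3,
        }
    )
    cfg = SimulationConfig(
        seed=9, kernels=kern, n_subjects=30, n_days=300, missing_rate=0.31
    )
    return latent_observed_panel(simulate_panel(cfg), cfg)


@pytest.fixture(scope="module")
def forward_comparison(full_mediation_panel):
    return run_mediation(
        full_mediation_panel, "sleep_duration", "negative_affect", "psychosis"
    )


def _result(verdict, bic=100.0):
    return MediationResult(
        "x", "m", "y", None, None, None, None,
        total_effect=-0.5, direct_effect=-0.1, indirect_effect=-0.4,
        direct_lags=(1,), path_b_lags=(1,),
        bic_unmediated=110.0, bic_mediated=bic, verdict=verdict,
    )


class TestVerdicts:
    def test_full_mediation_recovered(self, forward_comparison):
        fw = forward_comparison.forward
        assert fw.verdict == "full"
        assert fw.direct_effect == 0.0
        assert fw.indirect_effect == pytest.approx(fw.total_effect)
        assert fw.bic_mediated < fw.bic_unmediated

    def test_accounting_identity_exact(self, forward_comparison):
        for res in (forward_comparison.forward, forward_comparison.oppositional):
            assert res.total_effect == res.direct_effect + res.indirect_effect

    def test_oppositional_model_rejected(self, forward_comparison):
        assert forward_comparison.oppositional.verdict == "no mediation"
        assert forward_comparison.preferred == "forward"

    def test_independent_mediator_short_circuits(self):
        # M unrelated to X: path a n.s. -> verdict "no mediation"
        kern = LagKernel({("sleep_duration", "psychosis"): [-0.3] * 2})
        cfg = SimulationConfig(
            seed=17, kernels=kern, n_subjects=20, n_days=200, missing_rate=0.31
        )
        sp = latent_observed_panel(simulate_panel(cfg), cfg)
        res = fit_mediated_model(
            sp, "sleep_duration", "negative_affect", "psychosis"
        )
        assert res.verdict == "no mediation"
        assert "path" in res.note
        assert res.indirect_effect == 0.0

    def test_degenerate_triples_rejected(self, full_mediation_panel):
        with pytest.raises(FitError, match="distinct"):
            fit_path_a(full_mediation_panel, "psychosis", "psychosis")
        with pytest.raises(FitError, match="distinct"):
            fit_mediated_model(
                full_mediation_panel, "sleep_duration", "sleep_duration", "psychosis"
            )


class TestComparisonRules:
    def test_tie_within_tolerance_is_inconclusive(self):
        cmp_ = compare_mediation(_result("full", 100.0), _result("full", 100.0 + 1e-9))
        assert cmp_.preferred == "inconclusive"

    def test_lower_bic_wins_when_both_mediate(self):
        cmp_ = compare_mediation(_result("partial", 90.0), _result("full", 100.0))
        assert cmp_.preferred == "forward"
        cmp_ = compare_mediation(_result("partial", 120.0), _result("full", 100.0))
        assert cmp_.preferred == "oppositional"

    def test_neither_mediates_is_inconclusive(self):
        cmp_ = compare_mediation(_result("no mediation"), _result("no mediation"))
        assert cmp_.preferred == "inconclusive"

    def test_single_indirect_pathway_decides(self):
        cmp_ = compare_mediation(_result("full"), _result("no mediation"))
        assert cmp_.preferred == "forward"


def test_path_diagram_names_all_paths(forward_comparison):
    text = path_diagram(forward_comparison.forward)
    for token in ("path a", "path b", "path c", "path c'", "verdict"):
        assert token in text
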