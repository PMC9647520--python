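"""Lag-space mediation analysis (Baron-Kenny with the joint significance test).

Procedure for a triple (predictor X, mediator M, outcome Y):

1. *Path a*: two-stage model of X -> M.  No significant lags short-circuits
   the analysis with verdict "no mediation" (the intermediate variable cannot
   act as a mediator).
2. *Total effect*: two-stage model of X -> Y.
3. *Path b lags*: the mediator's own predictive lags on Y are re-screened
   with a two-stage M -> Y model (the mediator enters the joint model at its
   own lags relative to Y, not at lags inherited from X).
4. *Mediated model*: X and M enter the outcome model jointly; backward
   elimination prunes both paths.  The direct effect is the summed beta over
   the retained X terms in this joint model; the indirect effect is total -
   direct (the difference method: with distinct lag sets per path, a
   product-of-paths over lag pairs is ill-defined).
5. Joint significance: mediation is claimed only when the retained lag sets
   of path a and path b are both non-empty.  Verdict "full" when the direct
   path is eliminated entirely, "partial" when it survives with |direct| <
   |total|.
6. BICs of the mediated and unmediated outcome models are compared on the
   same outcome observations (same conditioning window).
7. The *oppositional model* repeats everything with X and M exchanged; the
   more parsimonious account is the one with an indirect pathway under joint
   significance, with lower BIC as the tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .confirm import (
    FinalLagModel,
    LagModelFit,
    _package_fit,
    fit_outcome_model,
    iterate_two_stage,
    summed_effect,
)
from .ingest import StandardizedPanel
from .items import FitError
from .lagdesign import panel_arrays
from .lagsets import format_lag_runs

_BIC_TIE_TOL = 1e-6


@dataclass
class MediationResult:
    """Mediation analysis of one (predictor, mediator, outcome) triple."""

    predictor: str
    mediator: str
    outcome: str
    path_a: FinalLagModel | None
    total_model: FinalLagModel | None
    b_screen: FinalLagModel | None
    joint_table: pd.DataFrame | None
    total_effect: float
    direct_effect: float
    indirect_effect: float
    direct_lags: tuple[int, ...]
    path_b_lags: tuple[int, ...]
    bic_unmediated: float
    bic_mediated: float
    verdict: str  # "no mediation" | "partial" | "full"
    note: str = ""

    @property
    def has_indirect_pathway(self) -> bool:
        return self.verdict in ("partial", "full")

    def to_dict(self) -> dict:
        return {
            "triple": f"{self.predictor} -> {self.mediator} -> {self.outcome}",
            "path_a_lags": format_lag_runs(
                self.path_a.fit.cross["lag"] if self.path_a else ()
            ),
            "path_b_lags": format_lag_runs(self.path_b_lags),
            "direct_lags": format_lag_runs(self.direct_lags),
            "total_effect": self.total_effect,
            "direct_effect": self.direct_effect,
            "indirect_effect": self.indirect_effect,
            "bic_unmediated": self.bic_unmediated,
            "bic_mediated": self.bic_mediated,
            "verdict": self.verdict,
            "note": self.note,
        }


@dataclass
class MediationComparison:
    """Forward vs oppositional mediation models for one triple."""

    forward: MediationResult
    oppositional: MediationResult
    preferred: str  # "forward" | "oppositional" | "inconclusive"
    reason: str


def fit_path_a(
    panel: StandardizedPanel,
    predictor: str,
    mediator: str,
    max_lag: int = 20,
    alpha: float = 0.05,
    k: int = 19,
    **kwargs,
) -> FinalLagModel:
    """Two-stage final model for the predictor -> mediator path."""
    if predictor == mediator:
        raise FitError("predictor and mediator must be distinct variables")
    return iterate_two_stage(
        panel, predictor, mediator, max_lag=max_lag, alpha=alpha, k=k, **kwargs
    )


def _path_diagram(res: MediationResult) -> str:
    x, m, y = res.predictor, res.mediator, res.outcome
    a = format_lag_runs(res.path_a.fit.cross["lag"] if res.path_a else ())
    b = format_lag_runs(res.path_b_lags)
    c_tot = format_lag_runs(
        res.total_model.fit.cross["lag"] if res.total_model else ()
    )
    cp = format_lag_runs(res.direct_lags)
    return (
        f"path a  ({x} -> {m}): lags {a}\n"
        f"path b  ({m} -> {y} | {x}): lags {b}\n"
        f"path c  ({x} -> {y}, total): lags {c_tot}, "
        f"summed beta {res.total_effect:+.3f}\n"
        f"path c' ({x} -> {y} | {m}, direct): lags {cp}, "
        f"summed beta {res.direct_effect:+.3f}\n"
        f"indirect (c - c'): {res.indirect_effect:+.3f}   verdict: {res.verdict}"
    )


def fit_mediated_model(
    panel: StandardizedPanel,
    predictor: str,
    mediator: str,
    outcome: str,
    max_lag: int = 20,
    alpha: float = 0.05,
    k: int = 19,
    include_auto: bool = True,
    x_order: int = 1,
) -> MediationResult:
    """Full mediation procedure for one ordered triple."""
    if len({predictor, mediator, outcome}) < 3:
        raise FitError("predictor, mediator and outcome must be distinct")

    kw = dict(max_lag=max_lag, alpha=alpha, k=k, include_auto=include_auto, x_order=x_order)
    path_a = fit_path_a(panel, predictor, mediator, max_lag, alpha, k,
                        include_auto=include_auto, x_order=x_order)
    total = iterate_two_stage(panel, predictor, outcome, **kw)
    total_eff = summed_effect(total.fit)

    if not path_a.fit.significant:
        return MediationResult(
            predictor, mediator, outcome,
            path_a, total, None, None,
            total_effect=total_eff,
            direct_effect=total_eff,
            indirect_effect=0.0,
            direct_lags=total.fit.cross_lags.lags,
            path_b_lags=(),
            bic_unmediated=total.fit.bic,
            bic_mediated=np.nan,
            verdict="no mediation",
            note="path a n.s.; mediator cannot transmit an effect",
        )

    b_screen = iterate_two_stage(panel, mediator, outcome, **kw)
    if not b_screen.fit.significant:
        return MediationResult(
            predictor, mediator, outcome,
            path_a, total, b_screen, None,
            total_effect=total_eff,
            direct_effect=total_eff,
            indirect_effect=0.0,
            direct_lags=total.fit.cross_lags.lags,
            path_b_lags=(),
            bic_unmediated=total.fit.bic,
            bic_mediated=np.nan,
            verdict="no mediation",
            note="path b n.s. (mediator does not predict the outcome)",
        )

    # joint model: X and M simultaneously -> Y, on a common conditioning window
    data = panel_arrays(panel, [predictor, mediator, outcome])
    x_terms = [(predictor, l) for l in total.fit.cross_lags]
    m_terms = [(mediator, l) for l in b_screen.fit.cross_lags]
    auto_terms = [(outcome, m) for m in total.fit.auto_lags]
    a_lags = tuple(path_a.fit.cross_lags)
    nuisance = {
        predictor: tuple((predictor, j) for j in range(1, x_order + 1)),
        mediator: tuple((predictor, l) for l in a_lags)
        + tuple((mediator, j) for j in range(1, x_order + 1)),
    }
    all_lags = (
        [l for _, l in x_terms + m_terms + auto_terms]
        + list(a_lags)
        + [x_order]
    )
    window = max(all_lags)

    # total-effect model refitted on the same window for comparable BIC/effects
    table_u, em_u, _, _ = fit_outcome_model(
        data, outcome, x_terms + auto_terms,
        {predictor: nuisance[predictor]},
        alpha=alpha, eliminate=False, condition_lag=window,
    )
    fit_u = _package_fit(predictor, outcome, table_u, em_u, [], alpha)
    total_eff_cmp = summed_effect(fit_u)

    table_j, em_j, dropped_j, _ = fit_outcome_model(
        data, outcome, x_terms + m_terms + auto_terms, nuisance,
        alpha=alpha, eliminate=True, condition_lag=window,
    )
    retained_x = table_j[table_j["variable"] == predictor]
    retained_m = table_j[table_j["variable"] == mediator]
    direct_eff = float(retained_x["beta"].sum())
    direct_lags = tuple(int(l) for l in retained_x["lag"])
    path_b_lags = tuple(int(l) for l in retained_m["lag"])

    n_obs = em_j.n_by_var[outcome]
    n_params_j = len(table_j) + em_j.n_subjects + 1
    bic_j = float(-2.0 * em_j.loglik_by_var[outcome] + n_params_j * np.log(max(n_obs, 1)))

    indirect = total_eff_cmp - direct_eff
    if not path_b_lags:
        verdict, note = "no mediation", "path b eliminated in the joint model"
        direct_eff = total_eff_cmp
        indirect = 0.0
        direct_lags = tuple(int(l) for l in table_u[table_u["variable"] == predictor]["lag"])
    elif not direct_lags:
        verdict, note = "full", "direct path eliminated; indirect carries the effect"
        direct_eff = 0.0
        indirect = total_eff_cmp
    elif abs(direct_eff) < abs(total_eff_cmp):
        verdict, note = "partial", "direct path reduced but still significant"
    else:
        verdict, note = "no mediation", "direct effect not reduced by the mediator"

    return MediationResult(
        predictor, mediator, outcome,
        path_a, total, b_screen, table_j,
        total_effect=total_eff_cmp,
        direct_effect=direct_eff,
        indirect_effect=indirect,
        direct_lags=direct_lags,
        path_b_lags=path_b_lags,
        bic_unmediated=fit_u.bic,
        bic_mediated=bic_j,
        verdict=verdict,
        note=note,
    )


def fit_oppositional_model(
    panel: StandardizedPanel,
    predictor: str,
    mediator: str,
    outcome: str,
    **kwargs,
) -> MediationResult:
    """Same procedure with the predictor and mediator roles exchanged."""
    return fit_mediated_model(panel, mediator, predictor, outcome, **kwargs)


def compare_mediation(
    forward: MediationResult, oppositional: MediationResult
) -> MediationComparison:
    """Adjudicate which direction offers the more parsimonious account.

    Rule: (1) presence of an indirect pathway under joint significance, then
    (2) lower mediated BIC; identical BICs within tolerance -> inconclusive.
    """
    f, o = forward.has_indirect_pathway, oppositional.has_indirect_pathway
    if f and not o:
        return MediationComparison(
            forward, oppositional, "forward",
            "only the forward model shows an indirect pathway",
        )
    if o and not f:
        return MediationComparison(
            forward, oppositional, "oppositional",
            "only the oppositional model shows an indirect pathway",
        )
    if not f and not o:
        return MediationComparison(
            forward, oppositional, "inconclusive",
            "neither model shows an indirect pathway",
        )
    delta = oppositional.bic_mediated - forward.bic_mediated
    if not np.isfinite(delta) or abs(delta) < _BIC_TIE_TOL:
        return MediationComparison(
            forward, oppositional, "inconclusive",
            "both models show indirect pathways with equivalent fit",
        )
    if delta > 0:
        return MediationComparison(
            forward, oppositional, "forward",
            f"both models mediate; forward BIC lower by {delta:.3f}",
        )
    return MediationComparison(
        forward, oppositional, "oppositional",
        f"both models mediate; oppositional BIC lower by {-delta:.3f}",
    )


def run_mediation(
    panel: StandardizedPanel,
    predictor: str,
    mediator: str,
    outcome: str,
    **kwargs,
) -> MediationComparison:
    """Forward and oppositional mediation analyses plus the comparison."""
    forward = fit_mediated_model(panel, predictor, mediator, outcome, **kwargs)
    opposite = fit_oppositional_model(panel, predictor, mediator, outcome, **kwargs)
    return compare_mediation(forward, opposite)


def path_diagram(result: MediationResult) -> str:
    """Human-readable path diagram naming paths a, b, c and c'."""
    return _path_diagram(result)
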