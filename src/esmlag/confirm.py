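"""Confirmatory stage: discrete-lag dynamic models and the two-stage loop.

The confirmatory model is

    y_t = sum_{l in cross} beta_l x_{t-l} + sum_{m in auto} phi_m y_{t-m}
          + subject intercept + eps_t ,

fitted by Gaussian maximum likelihood in a state-space formulation whose
likelihood marginalizes over unobserved days (see :mod:`esmlag._statespace`).
Backward elimination drops the least-significant coefficient with p >= alpha
and refits until every retained coefficient is significant.  The two-stage
procedure alternates the exploratory screen (on the raw design, then on
residual-informed designs) with the confirmatory fit until the retained lag
set repeats; oscillation between two sets resolves to their intersection.

Reported log-likelihood and BIC refer to the outcome observations
(prediction-error decomposition); BIC = -2 loglik + n_params log(n_obs) with
n_params = retained coefficients + subject intercepts + innovation variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._statespace import DynamicFit, Equation, ModelParams, StateSpaceModel
from .explore import fit_smooth_lag, select_lags
from .ingest import StandardizedPanel
from .items import FitError
from .lagdesign import LagDesign, PanelData, build_lag_design, panel_arrays
from .lagsets import LagSet, format_lag_runs


@dataclass
class LagModelFit:
    """Confirmatory fit at a discrete lag set with per-lag inference."""

    predictor: str
    outcome: str
    cross: pd.DataFrame  # columns: lag, beta, se, z, p
    auto: pd.DataFrame
    loglik: float
    bic: float
    n_obs: int
    n_subjects: int
    sigma2: float
    alpha: float
    n_params: int
    dropped: list[tuple[str, int]] = field(default_factory=list)
    em: DynamicFit | None = None

    @property
    def cross_lags(self) -> LagSet:
        return LagSet(tuple(self.cross["lag"]), self.alpha)

    @property
    def auto_lags(self) -> LagSet:
        return LagSet(tuple(self.auto["lag"]), self.alpha)

    @property
    def significant(self) -> bool:
        return len(self.cross) > 0

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "lags": format_lag_runs(self.cross["lag"]),
            "auto_lags": format_lag_runs(self.auto["lag"]),
            "cross": self.cross.to_dict(orient="records"),
            "auto": self.auto.to_dict(orient="records"),
            "summed_beta": summed_effect(self),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


def summed_effect(fit: LagModelFit) -> float:
    """Sum of the retained cross-path beta coefficients (0 if none, n.s.)."""
    if fit.cross.empty:
        return 0.0
    return float(fit.cross["beta"].sum())


@dataclass
class FinalLagModel:
    """Two-stage final model with iteration trace and convergence status."""

    fit: LagModelFit
    trace: list[tuple[tuple[int, ...], tuple[int, ...]]]
    converged: bool
    oscillation_resolved: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.trace)


# --------------------------------------------------------------------------
def _warm_subset(params: ModelParams | None, outcome: str, terms, old_terms):
    """Carry coefficients for surviving terms across elimination refits."""
    if params is None:
        return None
    new = params.copy()
    keep = [old_terms.index(t) for t in terms]
    new.coefs[outcome] = params.coefs[outcome][keep]
    return new


def fit_outcome_model(
    data: PanelData,
    outcome: str,
    terms: list[tuple[str, int]],
    nuisance: dict[str, tuple[tuple[str, int], ...]],
    alpha: float = 0.05,
    eliminate: bool = True,
    condition_lag: int | None = None,
    subject_intercept: bool = True,
    warm: ModelParams | None = None,
    init_coefs: dict[tuple[str, int], float] | None = None,
    bic_refine: bool = True,
) -> tuple[pd.DataFrame, DynamicFit, list[tuple[str, int]], StateSpaceModel]:
    """Fit the outcome equation with optional backward elimination.

    ``terms`` are (variable, lag) parents of the outcome; ``nuisance`` maps
    every other modelled variable to its own parents.  Returns the per-term
    inference table, the EM fit, the dropped terms, and the final model.

    After Wald elimination at ``alpha``, ``bic_refine`` additionally prunes
    any coefficient whose removal lowers the outcome BIC (compared on a
    common conditioning window): a lag is only reported when it both tests
    significant and improves model parsimony, which is what keeps the
    two-stage procedure's family-wise error low despite both stages reading
    the same data.
    """
    dropped: list[tuple[str, int]] = []
    current = list(terms)
    params = warm

    def _build(cur, cond):
        eqs = [Equation(v, parents, False) for v, parents in nuisance.items()]
        eqs.append(Equation(outcome, tuple(cur), subject_intercept))
        return StateSpaceModel(eqs, data, condition_lag=cond)

    def _table(cur, beta, se):
        z = beta / se
        return pd.DataFrame(
            {
                "variable": [v for v, _ in cur],
                "lag": [l for _, l in cur],
                "beta": beta,
                "se": se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )

    def _bic_y(em_fit, n_terms):
        n = max(em_fit.n_by_var[outcome], 1)
        k = n_terms + em_fit.n_subjects + 1
        return -2.0 * em_fit.loglik_by_var[outcome] + k * np.log(n)

    # ---- stage 1: Wald backward elimination at alpha
    while True:
        model = _build(current, condition_lag)
        if params is None and init_coefs is not None:
            params = model.initial_params()
            params.coefs[outcome] = np.array(
                [init_coefs.get(t, 0.0) for t in current], dtype=float
            )
        # looser EM tolerance while candidates are still being pruned
        em = model.fit_em(
            init=params,
            tol=1e-6 if eliminate else 1e-8,
            max_iter=6 if eliminate else 200,
        )
        params = em.params
        if not current:
            table = pd.DataFrame(columns=["variable", "lag", "beta", "se", "z", "p"])
            return table, em, dropped, model

        if eliminate:
            # lower-bound p-values (complete-data information): a term
            # non-significant here is non-significant under the exact test
            # too, so it can be dropped without the costly exact information
            quick_p = _table(
                current,
                params.coefs[outcome],
                model.coef_quick_se(outcome, params, em.moments),
            )["p"].to_numpy()
            hopeless = [i for i, pv in enumerate(quick_p) if pv >= 0.5]
            if len(hopeless) == len(current):
                hopeless = hopeless[:-1]  # keep at least one for a last exact look
            if hopeless:
                old = list(current)
                for i in sorted(hopeless, reverse=True):
                    dropped.append(current[i])
                    current.pop(i)
                params = _warm_subset(params, outcome, current, old)
                continue
            worst = int(np.argmax(quick_p))
            if quick_p[worst] >= alpha:
                old = list(current)
                dropped.append(current.pop(worst))
                params = _warm_subset(params, outcome, current, old)
                continue
            # all candidates plausibly significant: converge tightly, then test
            em = model.fit_em(init=params, tol=1e-8)
            params = em.params
        se, _ = model.coef_inference(outcome, params, moments=em.moments)
        table = _table(current, params.coefs[outcome], se)
        if not eliminate:
            return table, em, dropped, model
        worst = int(np.argmax(table["p"].to_numpy()))
        if table["p"].iloc[worst] < alpha:
            break
        old = list(current)
        dropped.append(current.pop(worst))
        params = _warm_subset(params, outcome, current, old)

    if not bic_refine:
        return table, em, dropped, model

    # ---- stage 2: BIC refinement on a fixed conditioning window
    nuis_lags = [l for parents in nuisance.values() for _, l in parents]
    window = condition_lag
    if window is None:
        window = max([l for _, l in current] + nuis_lags + [1])
    model_c = _build(current, window)
    em_c = model_c.fit_em(init=params, tol=1e-8)
    bic_cur = _bic_y(em_c, len(current))
    se_c, _ = model_c.coef_inference(outcome, em_c.params, moments=em_c.moments)
    table_c = _table(current, em_c.params.coefs[outcome], se_c)
    changed = False
    while current:
        worst = int(np.argmax(table_c["p"].to_numpy()))
        trial = [t for i, t in enumerate(current) if i != worst]
        trial_params = _warm_subset(em_c.params, outcome, trial, current)
        model_t = _build(trial, window)
        em_t = model_t.fit_em(init=trial_params, tol=1e-8)
        bic_trial = _bic_y(em_t, len(trial))
        if bic_trial >= bic_cur - 1e-9:
            break
        dropped.append(current[worst])
        current = trial
        changed = True
        model_c, em_c, bic_cur = model_t, em_t, bic_trial
        if not current:
            table_c = pd.DataFrame(columns=["variable", "lag", "beta", "se", "z", "p"])
            break
        se_c, _ = model_c.coef_inference(outcome, em_c.params, moments=em_c.moments)
        table_c = _table(current, em_c.params.coefs[outcome], se_c)

    if not changed and condition_lag is None and window == max(
        [l for _, l in current] + nuis_lags + [1]
    ):
        return table, em, dropped, model
    # refit at the natural window of the refined set for reporting
    model_f = _build(current, condition_lag)
    em_f = model_f.fit_em(
        init=_warm_subset(em_c.params, outcome, current, current), tol=1e-8
    )
    if current:
        se_f, _ = model_f.coef_inference(outcome, em_f.params, moments=em_f.moments)
        table_f = _table(current, em_f.params.coefs[outcome], se_f)
    else:
        table_f = pd.DataFrame(columns=["variable", "lag", "beta", "se", "z", "p"])
    return table_f, em_f, dropped, model_f


def _package_fit(
    predictor: str,
    outcome: str,
    table: pd.DataFrame,
    em: DynamicFit,
    dropped,
    alpha: float,
) -> LagModelFit:
    cross = table[table["variable"] == predictor][["lag", "beta", "se", "z", "p"]]
    if predictor == outcome:
        auto = pd.DataFrame(columns=["lag", "beta", "se", "z", "p"])
    else:
        auto = table[table["variable"] == outcome][["lag", "beta", "se", "z", "p"]]
    n_obs = em.n_by_var[outcome]
    loglik = em.loglik_by_var[outcome]
    n_params = len(table) + em.n_subjects + 1  # coefs + intercepts + variance
    bic = -2.0 * loglik + n_params * np.log(max(n_obs, 1))
    return LagModelFit(
        predictor=predictor,
        outcome=outcome,
        cross=cross.reset_index(drop=True),
        auto=auto.reset_index(drop=True),
        loglik=float(loglik),
        bic=float(bic),
        n_obs=int(n_obs),
        n_subjects=em.n_subjects,
        sigma2=float(em.params.sig2[outcome]),
        alpha=alpha,
        n_params=n_params,
        dropped=list(dropped),
        em=em,
    )


def fit_lag_model(
    design: LagDesign,
    candidate_lags: "LagSet | tuple[int, ...]",
    auto_lags: "LagSet | tuple[int, ...]" = (),
    alpha: float = 0.05,
    x_order: int = 1,
    eliminate: bool = True,
    condition_lag: int | None = None,
    init_coefs: dict[tuple[str, int], float] | None = None,
    bic_refine: bool = True,
) -> LagModelFit:
    """Confirmatory fit of one predictor/outcome pair at candidate lags.

    The predictor's own dynamics enter as a nuisance AR(``x_order``) equation
    so that the likelihood can marginalize its missing days.
    """
    cand = tuple(candidate_lags)
    auto = tuple(auto_lags)
    if not cand and not auto:
        raise FitError("candidate lag set is empty")
    x, y = design.predictor, design.outcome
    if x == y:
        terms = [(y, l) for l in sorted(set(cand) | set(auto))]
        nuisance: dict[str, tuple] = {}
    else:
        terms = [(x, l) for l in cand] + [(y, m) for m in auto]
        nuisance = {x: tuple((x, k) for k in range(1, x_order + 1))}
    table, em, dropped, _ = fit_outcome_model(
        design.arrays,
        y,
        terms,
        nuisance,
        alpha=alpha,
        eliminate=eliminate,
        condition_lag=condition_lag,
        init_coefs=init_coefs,
        bic_refine=bic_refine,
    )
    if x == y and not table.empty:
        # auto-regression analysis: the self-path is the reported path
        table = table.assign(variable=x)
    fit = _package_fit(x, y, table, em, dropped, alpha)
    return fit


# ----------------------------------------------------------- residual screen
def _residual_panel(
    design: LagDesign, fit: LagModelFit
) -> "SimpleNamespace | None":
    """Panel of outcome residuals from the current confirmatory model.

    Residuals are computed on outcome days where every retained lag is
    observed; the returned object duck-types StandardizedPanel (``.data``
    holding the full predictor series plus a ``resid`` column).
    """
    arrays = design.arrays
    x, y = design.predictor, design.outcome
    xj = arrays.var_index(x)
    yj = xj if x == y else arrays.var_index(y)
    beta = dict(zip(fit.cross["lag"], fit.cross["beta"]))
    phi = dict(zip(fit.auto["lag"], fit.auto["beta"]))
    alpha_by_sid: dict[str, float] = {}
    if fit.em is not None and y in fit.em.params.alpha:
        alpha_by_sid = dict(zip(fit.em.subjects, fit.em.params.alpha[y]))
    frames = []
    for i, sid in enumerate(arrays.subjects):
        T = int(arrays.lengths[i])
        xv = arrays.values[i, :T, xj]
        yv = arrays.values[i, :T, yj]
        resid = yv.copy()
        for l, b in beta.items():
            lagged = np.full(T, np.nan)
            lagged[l:] = xv[: T - l]
            resid = resid - b * lagged
        for m, f in phi.items():
            lagged = np.full(T, np.nan)
            lagged[m:] = yv[: T - m]
            resid = resid - f * lagged
        resid = resid - alpha_by_sid.get(sid, 0.0)
        dates = arrays.start_dates[i] + pd.to_timedelta(np.arange(T), unit="D")
        frames.append(
            pd.DataFrame(
                {"subject_id": sid, "date": dates, x: xv, "resid": resid}
            )
        )
    data = pd.concat(frames, ignore_index=True)
    data = data.dropna(subset=[x, "resid"], how="all").reset_index(drop=True)
    if data["resid"].notna().sum() == 0:
        return None
    return SimpleNamespace(data=data)


def _screen(
    design: LagDesign, k: int, alpha: float
) -> tuple[tuple[int, ...], dict[int, float]]:
    fit = fit_smooth_lag(design, k=k, alpha=alpha)
    betas = dict(zip(fit.table["lag"], fit.table["beta"]))
    return select_lags(fit, alpha).lags, betas


def iterate_two_stage(
    panel: StandardizedPanel,
    predictor: str,
    outcome: str,
    max_lag: int = 20,
    alpha: float = 0.05,
    k: int = 19,
    include_auto: bool = True,
    max_iter: int = 10,
    x_order: int = 1,
) -> FinalLagModel:
    """Alternate exploratory screening and confirmatory fitting to a fixed point.

    Auto-regression analysis is the special case ``predictor == outcome``.
    Returns the final model once the retained lag set repeats; on oscillation
    the intersection of the two competing sets is taken and flagged.
    """
    design = build_lag_design(panel, predictor, outcome, max_lag)
    auto_design = (
        build_lag_design(panel, outcome, outcome, max_lag)
        if include_auto and predictor != outcome
        else None
    )
    cand_cross, beta_cross = _screen(design, k, alpha)
    cand_auto, beta_auto = (
        _screen(auto_design, k, alpha) if auto_design is not None else ((), {})
    )
    x_name = predictor if predictor != outcome else outcome
    init_coefs = {(x_name, l): beta_cross.get(l, 0.0) for l in cand_cross}
    init_coefs.update({(outcome, m): beta_auto.get(m, 0.0) for m in cand_auto})

    trace: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    prev: tuple[tuple[int, ...], tuple[int, ...]] | None = None
    fit: LagModelFit | None = None
    converged = False
    oscillation = False

    for _ in range(max_iter):
        if not cand_cross and not cand_auto:
            fit = _null_fit(design, alpha, x_order)
            trace.append(((), ()))
            converged = True
            break
        fit = fit_lag_model(
            design, cand_cross, cand_auto, alpha=alpha, x_order=x_order,
            init_coefs=init_coefs,
        )
        retained = (fit.cross_lags.lags, fit.auto_lags.lags)
        trace.append(retained)
        if retained == prev:
            converged = True
            break
        if retained in trace[:-2]:
            # oscillation between two solutions: conservative intersection
            other = trace[-2]
            cross_i = tuple(sorted(set(retained[0]) & set(other[0])))
            auto_i = tuple(sorted(set(retained[1]) & set(other[1])))
            oscillation = True
            if cross_i or auto_i:
                fit = fit_lag_model(
                    design, cross_i, auto_i, alpha=alpha, x_order=x_order,
                    eliminate=False,
                )
            else:
                fit = _null_fit(design, alpha, x_order)
            trace.append((cross_i, auto_i))
            converged = True
            break
        if not retained[0] and not retained[1]:
            converged = True
            break
        # residual-informed re-screen
        resid_panel = _residual_panel(design, fit)
        new_cross: tuple[int, ...] = ()
        new_auto: tuple[int, ...] = ()
        if resid_panel is not None:
            try:
                rdesign = build_lag_design(resid_panel, predictor, "resid", max_lag)
                new_cross = tuple(
                    l for l in _screen(rdesign, k, alpha)[0] if l not in retained[0]
                )
            except FitError:
                new_cross = ()
        if auto_design is not None and resid_panel is not None:
            try:
                merged = resid_panel.data.copy()
                adesign = build_lag_design(
                    SimpleNamespace(data=_with_outcome(merged, design)), outcome, "resid", max_lag
                )
                new_auto = tuple(
                    m for m in _screen(adesign, k, alpha)[0] if m not in retained[1]
                )
            except FitError:
                new_auto = ()
        if not new_cross and not new_auto:
            converged = True
            break
        prev = retained
        cand_cross = tuple(sorted(set(retained[0]) | set(new_cross)))
        cand_auto = tuple(sorted(set(retained[1]) | set(new_auto)))
        init_coefs = {
            (x_name, int(r.lag)): float(r.beta) for r in fit.cross.itertuples()
        }
        init_coefs.update(
            {(outcome, int(r.lag)): float(r.beta) for r in fit.auto.itertuples()}
        )

    assert fit is not None
    return FinalLagModel(fit, trace, converged, oscillation)


def _with_outcome(resid_df: pd.DataFrame, design: LagDesign) -> pd.DataFrame:
    """Attach the outcome's own series to a residual frame for auto screening."""
    arrays = design.arrays
    yj = arrays.var_index(design.outcome)
    rows = []
    for i, sid in enumerate(arrays.subjects):
        T = int(arrays.lengths[i])
        yv = arrays.values[i, :T, yj]
        t_idx = np.where(np.isfinite(yv))[0]
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "date": arrays.start_dates[i] + pd.to_timedelta(t_idx, unit="D"),
                    design.outcome: yv[t_idx],
                }
            )
        )
    ydf = pd.concat(rows, ignore_index=True)
    return pd.merge(resid_df, ydf, how="outer")


def _null_fit(design: LagDesign, alpha: float, x_order: int) -> LagModelFit:
    """Intercept-only outcome model (no significant lags; reported n.s.)."""
    x, y = design.predictor, design.outcome
    nuisance = (
        {} if x == y else {x: tuple((x, k) for k in range(1, x_order + 1))}
    )
    table, em, dropped, _ = fit_outcome_model(
        design.arrays, y, [], nuisance, alpha=alpha, eliminate=False
    )
    return _package_fit(x, y, table, em, dropped, alpha)
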