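"""Gaussian state-space maximum likelihood for structured lagged models.

Each modelled variable gets one equation: current value = linear combination
of (variable, lag) parents + optional subject intercept + Gaussian innovation.
The state stacks each variable's current and lagged values; observed entries
are exact observations of the corresponding state slots, and missing days are
simply absent observation rows, so the Kalman filter marginalizes over them.

Estimation is EM: the E-step is a batched Kalman filter/smoother over
subjects, the M-step closed-form regressions on smoothed moments.  The
likelihood conditions on each subject's first ``condition_lag`` days (initial
state built from the observed history; unobserved entries get unit variance,
the stationary variance of person-standardized data), which makes the
complete-data case coincide exactly with OLS-with-subject-dummies.

Per-variable innovation log-likelihoods are accumulated by updating parents
before the outcome at every time step, so the outcome component is a genuine
prediction-error decomposition and, with complete data, equals the
closed-form Gaussian regression log-likelihood.

Standard errors come from the observed-data information, obtained by central
finite differences of the Fisher-identity score (one smoother pass per
perturbation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kalman import em_pass
from .items import FitError
from .lagdesign import PanelData

_JITTER = 1e-9
_SIG_FLOOR = 1e-10


@dataclass(frozen=True)
class Equation:
    """One structural equation: target's current value on lagged parents."""

    target: str
    parents: tuple[tuple[str, int], ...] = ()
    subject_intercept: bool = False

    def __post_init__(self) -> None:
        for var, lag in self.parents:
            if lag < 1:
                raise FitError(f"parent lag must be >= 1, got ({var}, {lag})")


@dataclass
class ModelParams:
    """Coefficients, innovation variances, subject intercepts."""

    coefs: dict[str, np.ndarray]
    sig2: dict[str, float]
    alpha: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: v.copy() for k, v in self.coefs.items()},
            dict(self.sig2),
            {k: v.copy() for k, v in self.alpha.items()},
        )


@dataclass
class DynamicFit:
    """Converged EM fit with per-variable observation log-likelihoods."""

    params: ModelParams
    loglik_by_var: dict[str, float]
    n_by_var: dict[str, int]
    n_iter: int
    converged: bool
    n_subjects: int
    subjects: list[str] = field(default_factory=list)
    moments: tuple | None = None  # cached (sum_z, sum_zz, counts) at the MLE


class StateSpaceModel:
    def __init__(
        self,
        equations: list[Equation],
        data: PanelData,
        condition_lag: int | None = None,
    ):
        self.equations = {eq.target: eq for eq in equations}
        self.var_order = [eq.target for eq in equations]
        for eq in equations:
            for var, _ in eq.parents:
                if var not in self.equations:
                    raise FitError(f"parent variable {var!r} has no equation")
            if eq.target not in data.variables:
                raise FitError(f"variable {eq.target!r} absent from panel data")

        # slot layout: per variable, lags 0..L_v
        max_parent_lag: dict[str, int] = {v: 0 for v in self.var_order}
        for eq in equations:
            for var, lag in eq.parents:
                max_parent_lag[var] = max(max_parent_lag[var], lag)
        self.slots: list[tuple[str, int]] = []
        for v in self.var_order:
            for l in range(max_parent_lag[v] + 1):
                self.slots.append((v, l))
        self.slot_index = {s: i for i, s in enumerate(self.slots)}
        self.d = len(self.slots)
        all_lags = [lag for eq in equations for _, lag in eq.parents]
        self.condition_lag = condition_lag if condition_lag is not None else max(all_lags, default=1)
        if all_lags and self.condition_lag < max(all_lags):
            raise FitError("condition_lag smaller than the largest parent lag")

        # restrict data to usable subjects and modelled variables
        vidx = [data.var_index(v) for v in self.var_order]
        usable = data.lengths > self.condition_lag + 1  # at least 2 modeled days
        if not np.any(usable):
            raise FitError("no usable rows: every subject shorter than the lag window")
        self.subjects = [s for s, u in zip(data.subjects, usable) if u]
        self.values = data.values[usable][:, :, vidx]
        self.lengths = data.lengths[usable]
        self.mask = np.isfinite(self.values)
        self.S = len(self.subjects)
        self.T = int(self.lengths.max())
        self._values64 = np.ascontiguousarray(
            np.nan_to_num(self.values, nan=0.0), dtype=np.float64
        )
        self._slot_var = np.array(
            [self.var_order.index(v) for v, _ in self.slots], np.int64
        )
        self._slot_lag = np.array([l for _, l in self.slots], np.int64)
        self._slot0 = np.array(
            [self.slot_index[(v, 0)] for v in self.var_order], np.int64
        )
        if not any(
            self.mask[:, self.condition_lag :, self.var_order.index(v)].any()
            for v in self.var_order
        ):
            raise FitError("no usable rows after conditioning window")

    # ---------------------------------------------------------------- helpers
    def _csr(self, params: ModelParams):
        """CSR transition matrix, innovation diag and intercept shifts."""
        d = self.d
        indptr = np.zeros(d + 1, np.int64)
        cols: list[int] = []
        vals: list[float] = []
        for i, (v, l) in enumerate(self.slots):
            if l == 0:
                eq = self.equations[v]
                for (pvar, lag), c in zip(eq.parents, params.coefs[v]):
                    cols.append(self.slot_index[(pvar, lag - 1)])
                    vals.append(float(c))
            else:
                cols.append(self.slot_index[(v, l - 1)])
                vals.append(1.0)
            indptr[i + 1] = len(cols)
        Qd = np.zeros(d)
        for v in self.var_order:
            Qd[self.slot_index[(v, 0)]] = max(params.sig2[v], _SIG_FLOOR)
        D = np.zeros((self.S, d))
        for v, a in params.alpha.items():
            D[:, self.slot_index[(v, 0)]] = a
        return (
            indptr,
            np.asarray(cols, np.int64),
            np.asarray(vals, np.float64),
            Qd,
            D,
        )

    def _pass(self, params: ModelParams, do_smooth: bool):
        indptr, indices, data, Qd, D = self._csr(params)
        ll_v, nobs_v, sum_z, sum_zz, counts = em_pass(
            self._values64,
            self.mask,
            self.lengths.astype(np.int64),
            self.condition_lag,
            indptr,
            indices,
            data,
            Qd,
            D,
            self._slot_var,
            self._slot_lag,
            self._slot0,
            do_smooth,
        )
        ll = {v: float(ll_v[i]) for i, v in enumerate(self.var_order)}
        nobs = {v: int(nobs_v[i]) for i, v in enumerate(self.var_order)}
        if not np.isfinite(sum(ll.values())):
            raise FitError("likelihood non-finite")
        return ll, nobs, sum_z, sum_zz, counts

    def _filter(self, params: ModelParams):
        ll, nobs, *_ = self._pass(params, do_smooth=False)
        return ll, nobs, None

    def _smoother_moments(self, params: ModelParams):
        """Per-subject sums of smoothed E[z], E[zz'] over equation times."""
        return self._pass(params, do_smooth=True)

    # ---------------------------------------------------------------- M-step
    def _m_step(self, sum_z, sum_zz, counts) -> ModelParams:
        coefs: dict[str, np.ndarray] = {}
        sig2: dict[str, float] = {}
        alpha: dict[str, np.ndarray] = {}
        N_total = counts
        for v in self.var_order:
            eq = self.equations[v]
            i = self.slot_index[(v, 0)]
            J = [self.slot_index[p] for p in eq.parents]
            n_all = float(N_total.sum())
            if not J:
                coefs[v] = np.zeros(0)
                if eq.subject_intercept:
                    a = np.where(counts > 0, sum_z[:, i] / np.maximum(counts, 1), 0.0)
                    alpha[v] = a
                    ss = sum_zz[:, i, i] - 2 * a * sum_z[:, i] + a * a * counts
                else:
                    ss = sum_zz[:, i, i]
                sig2[v] = max(float(ss.sum()) / max(n_all, 1.0), _SIG_FLOOR)
                continue
            A_JJ = sum_zz[np.ix_(range(self.S), J, J)]
            A_Ji = sum_zz[:, J, i]
            u_J = sum_z[:, J]
            u_i = sum_z[:, i]
            if eq.subject_intercept:
                w = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
                G = A_JJ.sum(axis=0) - np.einsum("s,sa,sb->ab", w, u_J, u_J)
                b = A_Ji.sum(axis=0) - (w * u_i) @ u_J
            else:
                G = A_JJ.sum(axis=0)
                b = A_Ji.sum(axis=0)
            try:
                c = np.linalg.solve(G, b)
            except np.linalg.LinAlgError:
                cond = np.linalg.cond(G)
                raise FitError(
                    f"singular design for equation {v!r} "
                    f"(condition number {cond:.3g})"
                ) from None
            coefs[v] = c
            if eq.subject_intercept:
                a = np.where(counts > 0, (u_i - u_J @ c) / np.maximum(counts, 1), 0.0)
                alpha[v] = a
            else:
                a = np.zeros(self.S)
            rss = (
                sum_zz[:, i, i]
                - 2 * A_Ji @ c
                + np.einsum("a,sab,b->s", c, A_JJ, c)
                - 2 * a * (u_i - u_J @ c)
                + a * a * counts
            )
            sig2[v] = max(float(rss.sum()) / max(n_all, 1.0), _SIG_FLOOR)
        return ModelParams(coefs, sig2, alpha)

    # --------------------------------------------------------------- scoring
    def _coef_score(self, target: str, params: ModelParams, sum_z, sum_zz, counts):
        """Fisher-identity score for one equation's coefficient block."""
        eq = self.equations[target]
        i = self.slot_index[(target, 0)]
        J = [self.slot_index[p] for p in eq.parents]
        c = params.coefs[target]
        a = params.alpha.get(target, np.zeros(self.S))
        sig2 = max(params.sig2[target], _SIG_FLOOR)
        A_JJ = sum_zz[np.ix_(range(self.S), J, J)]
        A_Ji = sum_zz[:, J, i]
        u_J = sum_z[:, J]
        g = A_Ji - np.einsum("sab,b->sa", A_JJ, c) - a[:, None] * u_J
        return g.sum(axis=0) / sig2

    def coef_quick_se(self, target: str, params: ModelParams, moments: tuple):
        """Lower-bound SEs from the complete-data information.

        The observed information never exceeds the complete-data information
        (Louis decomposition), so these SEs are never larger than the exact
        ones and the implied p-values never smaller: a term non-significant
        here is non-significant under the exact test as well.
        """
        eq = self.equations[target]
        J = [self.slot_index[p] for p in eq.parents]
        if not J:
            return np.zeros(0)
        sum_z, sum_zz, counts = moments
        A_JJ = sum_zz[np.ix_(range(self.S), J, J)]
        u_J = sum_z[:, J]
        if eq.subject_intercept:
            w = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
            G = A_JJ.sum(axis=0) - np.einsum("s,sa,sb->ab", w, u_J, u_J)
        else:
            G = A_JJ.sum(axis=0)
        sig2 = max(params.sig2[target], _SIG_FLOOR)
        w_eig, V = np.linalg.eigh(G / sig2)
        w_eig = np.maximum(w_eig, 1e-10)
        cov = (V / w_eig) @ V.T
        return np.sqrt(np.maximum(np.diag(cov), 1e-300))

    def coef_inference(self, target: str, params: ModelParams, moments: tuple | None = None):
        """Wald SEs for one equation's coefficients from observed information.

        One-sided finite differences of the Fisher-identity score around the
        MLE; ``moments`` may carry cached smoothed moments at ``params``.
        """
        c0 = params.coefs[target]
        p = c0.size
        if p == 0:
            return np.zeros(0), np.zeros((0, 0))
        if moments is None:
            _, _, sz, szz, cnt = self._smoother_moments(params)
            moments = (sz, szz, cnt)
        g0 = self._coef_score(target, params, *moments)
        info = np.zeros((p, p))
        for j in range(p):
            h = 1e-4 * (1.0 + abs(float(c0[j])))
            pert = params.copy()
            pert.coefs[target] = c0.copy()
            pert.coefs[target][j] += h
            _, _, sz, szz, cnt = self._smoother_moments(pert)
            g = self._coef_score(target, pert, sz, szz, cnt)
            info[:, j] = -(g - g0) / h
        info = 0.5 * (info + info.T)
        # guard: information must be positive definite
        w, V = np.linalg.eigh(info)
        w = np.maximum(w, 1e-10)
        cov = (V / w) @ V.T
        se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
        return se, cov

    # -------------------------------------------------------------------- EM
    def initial_params(self) -> ModelParams:
        """Complete-row OLS (pairwise fallback) starting values per equation."""
        coefs: dict[str, np.ndarray] = {}
        sig2: dict[str, float] = {}
        alpha: dict[str, np.ndarray] = {}
        for v in self.var_order:
            eq = self.equations[v]
            vi = self.var_order.index(v)
            J = eq.parents
            if not J:
                vals = self.values[:, :, vi]
                sig2[v] = float(np.nanvar(vals)) if np.isfinite(vals).any() else 1.0
                coefs[v] = np.zeros(0)
                if eq.subject_intercept:
                    alpha[v] = np.zeros(self.S)
                continue
            Lmax = max(l for _, l in J)
            ys, Xs = [], []
            for s in range(self.S):
                T = int(self.lengths[s])
                y = self.values[s, :T, vi]
                cols = []
                for pvar, lag in J:
                    pj = self.var_order.index(pvar)
                    col = np.full(T, np.nan)
                    col[lag:] = self.values[s, : T - lag, pj]
                    cols.append(col)
                X = np.column_stack(cols)
                ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
                ok[:Lmax] = False
                ys.append(y[ok])
                Xs.append(X[ok])
            y_all = np.concatenate(ys)
            X_all = np.vstack(Xs)
            if y_all.size >= max(30, 3 * len(J)):
                c, *_ = np.linalg.lstsq(X_all, y_all, rcond=None)
                resid = y_all - X_all @ c
                s2 = float(resid @ resid) / max(y_all.size - len(J), 1)
            else:
                # pairwise-complete single-lag slopes
                c = np.zeros(len(J))
                for jdx, (pvar, lag) in enumerate(J):
                    pj = self.var_order.index(pvar)
                    num = den = 0.0
                    for s in range(self.S):
                        T = int(self.lengths[s])
                        y = self.values[s, lag:T, vi]
                        x = self.values[s, : T - lag, pj]
                        ok = np.isfinite(y) & np.isfinite(x)
                        num += float(np.sum(x[ok] * y[ok]))
                        den += float(np.sum(x[ok] * x[ok]))
                    c[jdx] = num / den if den > 0 else 0.0
                s2 = 0.5
            coefs[v] = np.asarray(c, dtype=float)
            sig2[v] = max(s2, 1e-4)
            if eq.subject_intercept:
                alpha[v] = np.zeros(self.S)
        return ModelParams(coefs, sig2, alpha)

    def fit_em(
        self,
        init: ModelParams | None = None,
        max_iter: int = 200,
        tol: float = 1e-8,
    ) -> DynamicFit:
        params = init.copy() if init is not None else self.initial_params()
        prev_ll = -np.inf
        converged = False
        it = 0
        ll_by_var: dict[str, float] = {}
        n_by_var: dict[str, int] = {}
        moments: tuple = ()
        for it in range(1, max_iter + 1):
            ll_by_var, n_by_var, sum_z, sum_zz, counts = self._smoother_moments(params)
            moments = (sum_z, sum_zz, counts)
            ll = sum(ll_by_var.values())
            if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
                converged = True
                break
            prev_ll = ll
            params = self._m_step(sum_z, sum_zz, counts)
        return DynamicFit(
            params,
            ll_by_var,
            n_by_var,
            it,
            converged,
            self.S,
            list(self.subjects),
            moments=moments,
        )
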