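"""Exploratory stage: smooth coefficient function over the lag window.

On the long-stacked design the model is

    y_t = f(l) * x_{t-l} + subject intercept + error ,

with ``f`` a penalized cubic B-spline in the lag index (basis dimension ``k``,
difference penalty of configurable order, default 2).  The smoothing
parameter and the ridge on the subject-intercept block (the mixed-model
random intercept in penalized form) are chosen by generalized
cross-validation.  Because each outcome day is reused across the stacked lag
rows, pointwise Wald statistics use cluster-robust standard errors clustered
on (subject, day) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import norm

from .items import FitError
from .lagdesign import LagDesign
from .lagsets import LagSet


def bspline_basis(lags: np.ndarray, k: int, max_lag: int) -> np.ndarray:
    """Cubic B-spline basis of dimension ``k`` on the lag axis [1, max_lag]."""
    degree = 3
    if k < degree + 1:
        raise FitError(f"basis dimension k={k} too small (need >= {degree + 1})")
    interior = np.linspace(1, max_lag, k - 2)[1:-1]
    knots = np.concatenate([[1.0] * (degree + 1), interior, [float(max_lag)] * (degree + 1)])
    return BSpline.design_matrix(
        np.asarray(lags, dtype=float), knots, degree, extrapolate=False
    ).toarray()


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.eye(k)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D.T @ D


@dataclass
class SmoothLagFit:
    """Estimated beta(l) with pointwise uncertainty at each integer lag."""

    table: pd.DataFrame  # lag, beta, se, z, p
    k: int
    lam: float
    tau: float
    edf: float
    n: int
    subject_intercept_var: float
    gcv: float

    @property
    def lags(self) -> np.ndarray:
        return self.table["lag"].to_numpy()

    def to_csv(self, path) -> None:
        """Write the (lag, beta, se, z, p) fit table."""
        self.table.to_csv(path, index=False)


def fit_smooth_lag(
    design: LagDesign,
    k: int = 19,
    alpha: float = 0.05,
    penalty_order: int = 2,
    intercepts: str = "subject",
    se_method: str = "cluster",
    lam: float | None = None,
    tau: float | None = None,
    lam_grid: np.ndarray | None = None,
    tau_grid: np.ndarray | None = None,
    gcv_gamma: float = 1.4,
    selector: str = "bic",
) -> SmoothLagFit:
    """Fit the penalized varying-coefficient screen on the long lag design.

    ``lam``/``tau`` fix the smoothing parameters; left ``None`` they are
    selected by GCV on a log-spaced grid.  ``intercepts='none'`` drops the
    global and subject intercepts (useful on person-standardized data and for
    exact small-sample oracles).
    """
    long = design.long
    if long.empty:
        raise FitError("long lag design is empty")
    L = design.max_lag
    distinct = long["lag"].nunique()
    if distinct < 4:
        raise FitError(f"only {distinct} distinct lags with data (need >= 4)")
    k = min(k, L)

    lag_vals = long["lag"].to_numpy()
    x = long["x"].to_numpy()
    y = long["y"].to_numpy()
    n = y.size

    B_all = bspline_basis(np.arange(1, L + 1), k, L)  # (L, k)
    Xs = B_all[lag_vals - 1] * x[:, None]  # (n, k)

    use_int = intercepts == "subject"
    subj_codes, subj_uniques = pd.factorize(long["subject_id"], sort=True)
    S = len(subj_uniques) if use_int else 0

    # block cross-products without materializing dummy columns
    G_ss = Xs.T @ Xs
    c_s = Xs.T @ y
    yty = float(y @ y)
    if use_int:
        ns = np.bincount(subj_codes, minlength=S).astype(float)
        Xs_by_subj = np.zeros((S, k))
        np.add.at(Xs_by_subj, subj_codes, Xs)
        y_by_subj = np.bincount(subj_codes, weights=y, minlength=S)
        p = k + S + 1
        G = np.zeros((p, p))
        G[:k, :k] = G_ss
        G[:k, k : k + S] = Xs_by_subj.T
        G[k : k + S, :k] = Xs_by_subj
        G[k : k + S, k : k + S] = np.diag(ns)
        G[:k, -1] = Xs.sum(axis=0)
        G[-1, :k] = G[:k, -1]
        G[k : k + S, -1] = ns
        G[-1, k : k + S] = ns
        G[-1, -1] = n
        c = np.concatenate([c_s, y_by_subj, [y.sum()]])
    else:
        p = k
        G = G_ss
        c = c_s

    cl_codes, _ = pd.factorize(
        pd.util.hash_pandas_object(long[["subject_id", "date"]], index=False),
        sort=False,
    )
    n_clusters = int(cl_codes.max()) + 1

    S_pen = difference_penalty(k, penalty_order)

    def penalty(lam_v: float, tau_v: float) -> np.ndarray:
        P = np.zeros((p, p))
        P[:k, :k] = lam_v * S_pen
        if use_int:
            P[k : k + S, k : k + S] = tau_v * np.eye(S)
        return P

    def gcv_of(lam_v: float, tau_v: float) -> tuple[float, np.ndarray, float, float]:
        H = G + penalty(lam_v, tau_v)
        try:
            b = np.linalg.solve(H, c)
            edf = float(np.trace(np.linalg.solve(H, G)))
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(p), 0.0, np.inf
        rss = max(yty - 2 * b @ c + b @ G @ b, 1e-300)
        if selector == "bic":
            # df charged at log(n_clusters): smooths aggressively under the
            # null so that a flat (single-effective-test) curve is preferred
            score = n * np.log(rss / n) + np.log(max(n_clusters, 2)) * edf
        else:
            # gamma > 1 counters GCV's known tendency to undersmooth
            denom = max(n - gcv_gamma * edf, 1.0)
            score = n * rss / denom**2
        return score, b, edf, rss

    if lam is not None:
        lam_candidates = np.array([lam])
    else:
        lam_candidates = lam_grid if lam_grid is not None else np.logspace(-4, 8, 25)
    if not use_int or tau is not None:
        tau_candidates = np.array([tau if tau is not None else 0.0])
    else:
        tau_candidates = tau_grid if tau_grid is not None else np.logspace(-1, 4, 6)

    best = (np.inf, None, None, None, None)
    for lam_v in lam_candidates:
        for tau_v in tau_candidates:
            score, b, edf, rss = gcv_of(float(lam_v), float(tau_v))
            if score < best[0]:
                best = (score, float(lam_v), float(tau_v), b, (edf, rss))
    gcv_score, lam_sel, tau_sel, b, (edf, rss) = best
    if b is None or not np.all(np.isfinite(b)):
        raise FitError("singular design in exploratory fit")

    H = G + penalty(lam_sel, tau_sel)
    Hinv = np.linalg.inv(H)

    # residuals
    fitted = Xs @ b[:k]
    if use_int:
        fitted = fitted + b[k + subj_codes] + b[-1]
    e = y - fitted
    sigma2 = float(e @ e) / max(n - edf, 1.0)

    if se_method == "cluster":
        Gc = n_clusters
        U = np.zeros((Gc, p))
        np.add.at(U[:, :k], cl_codes, Xs * e[:, None])
        if use_int:
            e_by_cluster = np.bincount(cl_codes, weights=e, minlength=Gc)
            subj_of_cluster = np.zeros(Gc, dtype=int)
            subj_of_cluster[cl_codes] = subj_codes
            U[np.arange(Gc), k + subj_of_cluster] = e_by_cluster
            U[:, -1] = e_by_cluster
        meat = U.T @ U
        V = Hinv @ meat @ Hinv
    elif se_method == "model":
        V = sigma2 * (Hinv @ G @ Hinv)
    else:
        raise FitError(f"unknown se_method {se_method!r}")

    beta_l = B_all @ b[:k]
    V_sp = V[:k, :k]
    se_l = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B_all, V_sp, B_all), 1e-300))
    z = beta_l / se_l
    pvals = 2 * norm.sf(np.abs(z))

    table = pd.DataFrame(
        {"lag": np.arange(1, L + 1), "beta": beta_l, "se": se_l, "z": z, "p": pvals}
    )
    # lags with no observed pairs carry no evidence: mark non-significant
    empty_lags = design.pair_counts[design.pair_counts == 0].index
    table.loc[table["lag"].isin(empty_lags), "p"] = 1.0

    subj_var = float(np.var(b[k : k + S])) if use_int and S > 1 else 0.0
    return SmoothLagFit(table, k, lam_sel, tau_sel, float(edf), n, subj_var, gcv_score)


def select_lags(fit: SmoothLagFit, alpha: float = 0.05) -> LagSet:
    """Lags whose pointwise p-value falls below ``alpha`` (may be empty)."""
    flagged = fit.table.loc[fit.table["p"] < alpha, "lag"].tolist()
    return LagSet(tuple(flagged), alpha)
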