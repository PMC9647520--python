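"""Synthetic multi-subject daily diary panels with known lagged dynamics.

The generator emulates a year-long once-daily sleep and symptom diary study in
people living with psychosis: ~33 subjects followed for ~323 days with a ~69%
response rate, sleep quality on a 1-5 scale, sleep duration in hours (to the
nearest 15 min), fourteen 1-7 Likert symptom items, within-person
autocorrelation and cross-lagged coupling between variables over windows of up
to ~20 days, and subject-level heterogeneity as random intercepts.

Latent dynamics follow a linear Gaussian lagged recursion over six
composite-level variables

    x_t[v] = sum_{(s -> v)} sum_l beta_{s->v}(l) * x_{t-l}[s] + sigma_v eps_t ,

whose innovation variances are calibrated so every latent variable has unit
stationary variance; the configured kernels are therefore exact standardized
(per-SD) coefficients, which is what makes parameter recovery a well-posed
question downstream.  Diary items are the composite latent plus item-specific
noise, discretized through fixed equal-probability normal quantile bins.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .ingest import DiaryPanel, StandardizedPanel, standardize
from .items import COMPOSITES, LIKERT_LEVELS, SimulationError

#: latent variables carried by the recursion (composites + sleep fields)
LATENT_VARIABLES: list[str] = [
    "sleep_quality",
    "sleep_duration",
    "positive_affect",
    "negative_affect",
    "cognitive",
    "psychosis",
]

#: items generated from each latent composite (sleep fields map directly)
_ITEM_SOURCES: dict[str, str] = {}
for _comp in ("positive_affect", "negative_affect", "cognitive", "psychosis"):
    for _item in COMPOSITES[_comp]:
        _ITEM_SOURCES[_item] = _comp


class LagKernel:
    """Standardized coefficient vectors beta(l), l = 1..len, per variable pair.

    Unspecified pairs are implicitly all-zero.  All |beta(l)| must be < 1.
    """

    def __init__(self, pairs: dict[tuple[str, str], "np.ndarray | list[float]"]):
        clean: dict[tuple[str, str], np.ndarray] = {}
        for (src, tgt), beta in pairs.items():
            if src not in LATENT_VARIABLES or tgt not in LATENT_VARIABLES:
                raise SimulationError(f"unknown variable in kernel pair ({src}, {tgt})")
            vec = np.asarray(beta, dtype=float).ravel()
            if vec.size == 0:
                continue
            if np.any(np.abs(vec) >= 1.0):
                raise SimulationError(f"kernel ({src} -> {tgt}) has |beta| >= 1")
            clean[(src, tgt)] = vec
        self.pairs = clean

    @property
    def max_lag(self) -> int:
        return max((v.size for v in self.pairs.values()), default=1)

    def beta(self, src: str, tgt: str, max_lag: int) -> np.ndarray:
        """Coefficient vector for a pair, zero-padded to ``max_lag``."""
        out = np.zeros(max_lag)
        vec = self.pairs.get((src, tgt))
        if vec is not None:
            out[: vec.size] = vec[:max_lag]
        return out

    def to_dict(self) -> dict[str, list[float]]:
        return {f"{s}->{t}": list(map(float, v)) for (s, t), v in self.pairs.items()}

    @classmethod
    def from_dict(cls, d: dict[str, "list[float]"]) -> "LagKernel":
        pairs = {}
        for key, vec in d.items():
            src, tgt = key.split("->")
            pairs[(src.strip(), tgt.strip())] = vec
        return cls(pairs)


def _lag_matrices(kernel: LagKernel, max_lag: int) -> np.ndarray:
    """(L, V, V) array B with B[l-1][i, j] = beta_{var_j -> var_i}(l)."""
    V = len(LATENT_VARIABLES)
    B = np.zeros((max_lag, V, V))
    for (src, tgt), vec in kernel.pairs.items():
        i = LATENT_VARIABLES.index(tgt)
        j = LATENT_VARIABLES.index(src)
        B[: vec.size, i, j] = vec
    return B


def companion_matrix(kernel: LagKernel, max_lag: int | None = None) -> np.ndarray:
    """Companion matrix of the VAR implied by the kernel set."""
    L = max_lag or kernel.max_lag
    B = _lag_matrices(kernel, L)
    V = len(LATENT_VARIABLES)
    A = np.zeros((V * L, V * L))
    for l in range(L):
        A[:V, l * V : (l + 1) * V] = B[l]
    if L > 1:
        A[V:, : V * (L - 1)] = np.eye(V * (L - 1))
    return A


def spectral_radius(kernel: LagKernel, max_lag: int | None = None) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(kernel, max_lag)))))


def _calibrated_innovation_var(kernel: LagKernel, max_lag: int) -> np.ndarray:
    """Innovation variances giving each latent variable unit stationary variance.

    The stationary state covariance is linear in the (diagonal) innovation
    covariance, so the per-variable variance responses to unit innovations form
    a matrix M with diag(Sigma) = M q; solve M q = 1.
    """
    A = companion_matrix(kernel, max_lag)
    V = len(LATENT_VARIABLES)
    M = np.zeros((V, V))
    for j in range(V):
        Q = np.zeros_like(A)
        Q[j, j] = 1.0
        Sigma = solve_discrete_lyapunov(A, Q, method="bilinear")
        M[:, j] = np.diag(Sigma)[:V]
    q = np.linalg.solve(M, np.ones(V))
    if np.any(q <= 0):
        bad = [LATENT_VARIABLES[i] for i in np.where(q <= 0)[0]]
        raise SimulationError(
            "cannot calibrate unit variance: kernel dynamics alone push the "
            f"variance of {bad} to 1 or beyond; weaken the kernels"
        )
    return q


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic diary generator.

    Defaults mirror the sampling design being emulated: 33 subjects, 323 days,
    31% missing diaries, 5-level sleep quality, 7-level symptom items, sleep
    duration in hours quantized to 0.25 h.
    """

    seed: int
    kernels: LagKernel = field(default_factory=lambda: LagKernel({}))
    n_subjects: int = 33
    n_days: int = 323
    max_lag: int = 20
    innovation_sd: dict[str, float] | None = None  # None -> unit-variance calibration
    subject_intercept_sd: float = 0.5
    item_noise_sd: float = 0.5
    missing_rate: float = 0.31
    missingness_mode: str = "mcar"  # or "symptom"
    missing_slope: float = 0.5  # b in logistic(a + b * psychosis z), symptom mode
    likert_levels: dict[str, int] = field(default_factory=lambda: dict(LIKERT_LEVELS))
    duration_mean_hours: float = 8.0
    duration_sd_hours: float = 1.25
    burnin_factor: int = 3
    start_date: str = "2019-01-01"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise SimulationError("n_subjects and n_days must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must lie in [0, 1)")
        if self.missingness_mode not in ("mcar", "symptom"):
            raise SimulationError("missingness_mode must be 'mcar' or 'symptom'")
        if self.duration_mean_hours <= 0 or self.duration_sd_hours <= 0:
            raise SimulationError("duration mean/sd must be positive")
        if self.subject_intercept_sd < 0:
            raise SimulationError("subject_intercept_sd must be non-negative")
        L = max(self.max_lag, self.kernels.max_lag)
        rho = spectral_radius(self.kernels, L)
        if rho >= 1.0 - 1e-8:
            worst = max(
                self.kernels.pairs.items(),
                key=lambda kv: float(np.sum(np.abs(kv[1]))),
            )[0]
            raise SimulationError(
                f"non-stationary kernel set (spectral radius {rho:.3f} >= 1); "
                f"largest kernel: {worst[0]} -> {worst[1]}"
            )
        object.__setattr__(self, "_spectral_radius", rho)

    @property
    def effective_max_lag(self) -> int:
        return max(self.max_lag, self.kernels.max_lag)

    def innovation_variances(self) -> np.ndarray:
        """Per-variable innovation variances actually used by the recursion."""
        if self.innovation_sd is None:
            return _calibrated_innovation_var(self.kernels, self.effective_max_lag)
        q = np.array(
            [float(self.innovation_sd.get(v, 1.0)) ** 2 for v in LATENT_VARIABLES]
        )
        if np.any(q < 0):
            raise SimulationError("innovation_sd must be non-negative")
        return q

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernels"] = self.kernels.to_dict()
        return d


@dataclass
class TruePanel:
    """Latent continuous series plus (optionally) discretized/observed views."""

    config: SimulationConfig
    latent: pd.DataFrame  # subject_id, date, one column per latent variable
    diary: pd.DataFrame | None = None  # diary-scale values (post-discretization)
    observed: DiaryPanel | None = None  # after missingness

    def latent_wide(self, variable: str) -> pd.DataFrame:
        return self.latent.pivot(index="date", columns="subject_id", values=variable)


def simulate_panel(config: SimulationConfig) -> TruePanel:
    """Run the latent recursion; burn-in of ``burnin_factor * L`` days discarded."""
    rng = np.random.default_rng([int(config.seed), 0])
    V = len(LATENT_VARIABLES)
    L = config.effective_max_lag
    S, T = config.n_subjects, config.n_days
    burn = config.burnin_factor * L
    B = _lag_matrices(config.kernels, L)
    sd = np.sqrt(config.innovation_variances())

    total = L + burn + T
    x = np.zeros((S, total, V))
    eps = rng.normal(size=(S, total, V)) * sd
    for t in range(L, total):
        acc = eps[:, t, :].copy()
        for l in range(1, L + 1):
            if np.any(B[l - 1]):
                acc += x[:, t - l, :] @ B[l - 1].T
        x[:, t, :] = acc
    latent = x[:, L + burn :, :]

    if config.subject_intercept_sd > 0:
        latent = latent + config.subject_intercept_sd * rng.normal(size=(S, 1, V))

    subjects = [f"S{i + 1:02d}" for i in range(S)]
    dates = pd.date_range(config.start_date, periods=T, freq="D")
    frames = []
    for i, sid in enumerate(subjects):
        df = pd.DataFrame(latent[i], columns=LATENT_VARIABLES)
        df.insert(0, "date", dates)
        df.insert(0, "subject_id", sid)
        frames.append(df)
    return TruePanel(config=config, latent=pd.concat(frames, ignore_index=True))


def _person_standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(values)
    return (values - mu) / sd


def _likert(z: np.ndarray, levels: int) -> np.ndarray:
    """Equal-probability normal-quantile bins of a standardized latent."""
    thresholds = ndtri(np.arange(1, levels) / levels)
    return 1 + np.searchsorted(thresholds, z, side="left")


def discretize_to_likert(panel: TruePanel, config: SimulationConfig) -> TruePanel:
    """Map latent series onto the diary scales (Likert levels, 0.25-h hours)."""
    rng = np.random.default_rng([int(config.seed), 1])
    latent = panel.latent
    out = latent[["subject_id", "date"]].copy()

    groups = latent.groupby("subject_id", sort=False)

    q = np.concatenate([_person_standardize(g["sleep_quality"].to_numpy()) for _, g in groups])
    out["sleep_quality"] = _likert(q, config.likert_levels.get("sleep_quality", 5))

    dur = (
        config.duration_mean_hours
        + config.duration_sd_hours * latent["sleep_duration"].to_numpy()
    )
    out["sleep_duration"] = np.round(np.clip(dur, 0.0, 16.0) * 4) / 4  # 15-min grid

    for item, comp in _ITEM_SOURCES.items():
        noisy = latent[comp].to_numpy() + config.item_noise_sd * rng.normal(
            size=len(latent)
        )
        z = np.concatenate(
            [
                _person_standardize(noisy[latent["subject_id"].to_numpy() == sid])
                for sid in latent["subject_id"].unique()
            ]
        )
        out[item] = _likert(z, config.likert_levels.get(item, 7))

    return TruePanel(config=config, latent=panel.latent, diary=out, observed=panel.observed)


def _keep_mask(panel: TruePanel, config: SimulationConfig) -> np.ndarray:
    """Boolean per-row retention mask implementing the missingness model."""
    if config.missing_rate >= 1.0:
        raise SimulationError("missing_rate must be < 1")
    rng = np.random.default_rng([int(config.seed), 2])
    n = len(panel.latent)
    if config.missing_rate == 0:
        return np.ones(n, dtype=bool)
    if config.missingness_mode == "mcar":
        p_drop = np.full(n, config.missing_rate)
    else:
        sid = panel.latent["subject_id"].to_numpy()
        psych = panel.latent["psychosis"].to_numpy()
        z = np.concatenate(
            [_person_standardize(psych[sid == s]) for s in panel.latent["subject_id"].unique()]
        )
        b = config.missing_slope

        def marginal(a: float) -> float:
            return float(expit(a + b * z).mean()) - config.missing_rate

        a = brentq(marginal, -30.0, 30.0)
        p_drop = expit(a + b * z)
    return rng.uniform(size=n) > p_drop


def apply_missingness(panel: TruePanel, config: SimulationConfig) -> DiaryPanel:
    """Drop subject-days per the missingness model; absent rows, not sentinels."""
    if panel.diary is None:
        raise SimulationError("discretize_to_likert must run before apply_missingness")
    keep = _keep_mask(panel, config)
    observed = panel.diary.loc[keep].reset_index(drop=True)
    dp = DiaryPanel(observed)
    panel.observed = dp
    return dp


def latent_observed_panel(panel: TruePanel, config: SimulationConfig) -> StandardizedPanel:
    """Person-standardized panel of the *latent* series after missingness.

    Bypasses Likert discretization: used when estimator behaviour is to be
    assessed without the attenuation introduced by coarse diary scales.
    """
    keep = _keep_mask(panel, config)
    observed = panel.latent.loc[keep].reset_index(drop=True)
    return standardize(DiaryPanel(observed), variables=LATENT_VARIABLES)


def write_ground_truth(panel: TruePanel, path: "str | Path") -> None:
    """JSON sidecar with the generating kernels and configuration."""
    payload = {
        "config": panel.config.to_dict(),
        "kernels": panel.config.kernels.to_dict(),
        "innovation_variances": {
            v: float(q)
            for v, q in zip(LATENT_VARIABLES, panel.config.innovation_variances())
        },
        "spectral_radius": spectral_radius(
            panel.config.kernels, panel.config.effective_max_lag
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
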