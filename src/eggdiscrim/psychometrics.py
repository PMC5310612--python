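"""Binomial psychometric models of rejection probability.

Fits binary-response GLMs under logit, probit and complementary log-log
links by iteratively reweighted least squares, computes fit diagnostics
(Nagelkerke R^2, AICc, VIF, likelihood-ratio chi^2), and locates decision
thresholds at rejection probability 0.50 with bootstrap uncertainty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "LINKS",
    "TrialTable",
    "GLMFit",
    "FitDiagnostics",
    "ThresholdEstimate",
    "fit_binomial_glm",
    "fit_diagnostics",
    "threshold_location",
    "bootstrap_threshold",
]

logger = logging.getLogger(__name__)

LINKS = ("logit", "probit", "cloglog")

_EPS_MU = 1e-10
_MAX_ABS_BETA = 15.0
_IRLS_TOL = 1e-8
_IRLS_MAXITER = 50

#: Columns a full trial table carries (modelled columns must be complete).
TRIAL_COLUMNS = (
    "nest_id",
    "response",
    "x_bgbr",
    "x_gp",
    "x_uv",
    "chromatic_contrast",
    "achromatic_contrast",
    "flushed",
    "clutch_size",
    "laying_date",
    "nest_age",
)


@dataclass
class TrialTable:
    """One row per nest: binary response plus colour and nuisance covariates."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "response" not in self.df.columns:
            raise ValueError("trial table needs a 'response' column")
        resp = self.df["response"].to_numpy()
        if not np.isin(resp, (0, 1)).all():
            raise ValueError("response must be binary 0/1")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path) -> "TrialTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.12g")

    def require(self, columns: list[str]) -> None:
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if self.df[columns].isna().any().any():
            raise ValueError("missing values in modelled columns")


@dataclass
class GLMFit:
    link: str
    predictors: tuple[str, ...]  # non-intercept terms, design order
    beta: np.ndarray  # intercept first
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    loglik_null: float
    deviance: float
    n: int
    k: int
    converged: bool
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)


@dataclass
class FitDiagnostics:
    nagelkerke_r2: float
    aicc: float
    vif: dict[str, float]
    model_chi2: float
    model_df: int
    model_p: float


@dataclass
class ThresholdEstimate:
    point: float
    boot_median: float
    boot_iqr: float
    B: int
    n_failed: int
    seed: int
    reliable: bool


# ---------------------------------------------------------------------------
# Link functions: inverse link, derivative dmu/deta, link g(mu)


def _link_funcs(link: str):
    if link == "logit":
        inv = special.expit
        dmu = lambda eta, mu: mu * (1.0 - mu)
        g = lambda mu: np.log(mu / (1.0 - mu))
    elif link == "probit":
        inv = lambda eta: stats.norm.cdf(eta)
        dmu = lambda eta, mu: stats.norm.pdf(eta)
        g = lambda mu: stats.norm.ppf(mu)
    elif link == "cloglog":
        inv = lambda eta: -np.expm1(-np.exp(np.minimum(eta, 700.0)))
        dmu = lambda eta, mu: np.exp(eta - np.exp(np.minimum(eta, 700.0)))
        g = lambda mu: np.log(-np.log(1.0 - mu))
    else:
        raise ValueError(f"unknown link {link!r}; choose from {LINKS}")
    return inv, dmu, g


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _EPS_MU, 1.0 - _EPS_MU)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _irls(X: np.ndarray, y: np.ndarray, link: str):
    """Core IRLS loop; returns (beta, vcov, loglik, deviance, converged)."""
    inv, dmu, g = _link_funcs(link)
    n, k = X.shape
    mu = (y + 0.5) / 2.0
    eta = g(np.clip(mu, _EPS_MU, 1.0 - _EPS_MU))
    dev_old = np.inf
    beta = np.zeros(k)
    beta_old = beta
    converged = False
    XtWX = np.eye(k)
    for _ in range(_IRLS_MAXITER):
        d = dmu(eta, mu)
        d = np.clip(d, 1e-12, None)
        var = np.clip(mu * (1.0 - mu), _EPS_MU, None)
        w = d * d / var
        z = eta + (y - mu) / d
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ z)
        eta = X @ beta
        mu = np.clip(inv(eta), _EPS_MU, 1.0 - _EPS_MU)
        dev = -2.0 * _bernoulli_loglik(y, mu)
        # deviance tolerance plus a coefficient criterion: Fisher scoring
        # converges quadratically near the optimum, so the extra iterations
        # cost little and pin beta itself, not just the deviance
        if abs(dev_old - dev) < _IRLS_TOL and np.max(np.abs(beta - beta_old)) < 1e-9:
            converged = True
            break
        dev_old = dev
        beta_old = beta
    if np.max(np.abs(beta)) > _MAX_ABS_BETA:
        converged = False
    loglik = _bernoulli_loglik(y, np.clip(inv(X @ beta), _EPS_MU, 1.0 - _EPS_MU))
    vcov = np.linalg.inv(XtWX)
    return beta, vcov, loglik, -2.0 * loglik, converged


def _null_loglik(y: np.ndarray) -> float:
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return n * (p * np.log(p) + (1 - p) * np.log(1 - p))


def fit_binomial_glm(
    t: TrialTable, predictors: list[str], link: str = "logit"
) -> GLMFit:
    """Maximum-likelihood binomial GLM (intercept always included).

    IRLS to a deviance-change tolerance of 1e-8 within 50 iterations;
    standard errors from the inverse Fisher information at the optimum.
    Non-convergence or |beta| > 15 flags possible separation: the fit is
    returned with ``converged=False`` and a warning, never dropped.
    """
    predictors = list(predictors)
    t.require(["response", *predictors])
    y = t.df["response"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y))] + [t.df[p].to_numpy(dtype=float) for p in predictors]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    n, k = X.shape
    if n < k + 2:
        raise ValueError("too few rows for the requested model")
    beta, vcov, loglik, deviance, converged = _irls(X, y, link)
    if not converged:
        warnings.warn(
            "possible separation: IRLS did not converge or |beta| > 15",
            stacklevel=2,
        )
    se = np.sqrt(np.diag(vcov))
    return GLMFit(
        link=link,
        predictors=tuple(predictors),
        beta=beta,
        se=se,
        vcov=vcov,
        loglik=loglik,
        loglik_null=_null_loglik(y),
        deviance=deviance,
        n=n,
        k=k,
        converged=converged,
        X=X,
        y=y,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _vif(X: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """Variance inflation by OLS of each predictor on the others."""
    out: dict[str, float] = {}
    P = X[:, 1:]
    for j, name in enumerate(names):
        xj = P[:, j]
        others = np.delete(P, j, axis=1)
        Z = np.column_stack([np.ones(len(xj)), others])
        coef, *_ = np.linalg.lstsq(Z, xj, rcond=None)
        resid = xj - Z @ coef
        sst = np.sum((xj - xj.mean()) ** 2)
        if sst < 1e-300:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        out[name] = float(1.0 / max(1.0 - r2, 1e-12))
    return out


def fit_diagnostics(f: GLMFit) -> FitDiagnostics:
    """Nagelkerke R^2, AICc, VIF and whole-model likelihood-ratio test."""
    n, k = f.n, f.k
    ll0, ll1 = f.loglik_null, f.loglik
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    denom = 1.0 - np.exp((2.0 / n) * ll0)
    r2 = float(cox_snell / denom) if denom > 0 else 0.0
    chi2 = max(2.0 * (ll1 - ll0), 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return FitDiagnostics(
        nagelkerke_r2=r2,
        aicc=aicc(ll1, k, n),
        vif=_vif(f.X, f.predictors),
        model_chi2=float(chi2),
        model_df=df,
        model_p=p,
    )


_LINK_AT_HALF = {"logit": 0.0, "probit": 0.0, "cloglog": np.log(np.log(2.0))}


def threshold_location(f: GLMFit) -> float:
    """Predictor value at rejection probability 0.50.

    Requires an intercept-plus-one-predictor fit; x* = (g(0.5) - b0)/b1,
    with g(0.5) = 0 for logit/probit and ln(ln 2) for cloglog.
    """
    if len(f.predictors) != 1:
        raise ValueError("threshold defined for single-predictor models only")
    b0, b1 = f.beta
    if abs(b1) < 1e-8:
        raise ValueError("threshold undefined (flat psychometric function)")
    return float((_LINK_AT_HALF[f.link] - b0) / b1)


def bootstrap_threshold(
    t: TrialTable,
    predictor: str,
    link: str = "logit",
    B: int = 10_000,
    seed: int = 0,
) -> ThresholdEstimate:
    """Case-resampling bootstrap of the p=0.50 threshold.

    Each replicate resamples n rows with replacement, refits the
    intercept-plus-predictor model, and records its threshold; failed or
    separated replicates are dropped and counted.  Median and IQR use
    linear-interpolation quantiles.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    t.require(["response", predictor])
    y = t.df["response"].to_numpy(dtype=float)
    x = t.df[predictor].to_numpy(dtype=float)
    n = len(y)
    X_full = np.column_stack([np.ones(n), x])
    beta, *_rest = _irls(X_full, y, link)
    point = float((_LINK_AT_HALF[link] - beta[0]) / beta[1]) if abs(beta[1]) >= 1e-8 else np.nan

    rng = np.random.default_rng(seed)
    thresholds = np.empty(B)
    n_failed = 0
    kept = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        yb, xb = y[idx], x[idx]
        try:
            Xb = np.column_stack([np.ones(n), xb])
            bb, _, _, _, conv = _irls(Xb, yb, link)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        if not conv or abs(bb[1]) < 1e-8:
            n_failed += 1
            continue
        thresholds[kept] = (_LINK_AT_HALF[link] - bb[0]) / bb[1]
        kept += 1
    if kept == 0:
        raise RuntimeError("all bootstrap replicates failed")
    vals = thresholds[:kept]
    med = float(np.median(vals))
    q1, q3 = np.percentile(vals, [25, 75])
    reliable = n_failed < 0.5 * B
    if not reliable:
        logger.warning(
            "bootstrap threshold unreliable: %d/%d replicates failed",
            n_failed,
            B,
        )
    return ThresholdEstimate(
        point=point,
        boot_median=med,
        boot_iqr=float(q3 - q1),
        B=B,
        n_failed=n_failed,
        seed=seed,
        reliable=reliable,
    )
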