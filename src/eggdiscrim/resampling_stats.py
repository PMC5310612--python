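"""Slope-resampling comparison of discrimination ability.

90% subsample resampling of psychometric slopes, Monte-Carlo (Lilliefors
style) Kolmogorov-Smirnov normality testing, and a Wilcoxon rank-sum test
with rank-biserial effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_selection import SINGLE_THRESHOLD_PREDICTORS
from .psychometrics import TrialTable, _irls

__all__ = [
    "SlopeSample",
    "KSResult",
    "RankTestResult",
    "resample_slopes",
    "ks_normality_mc",
    "wilcoxon_rank_sum",
]


@dataclass
class SlopeSample:
    values: np.ndarray
    B: int
    fraction: float
    seed: int
    n_failed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.B - self.n_failed:
            raise ValueError("length must equal B - n_failed")


@dataclass
class KSResult:
    D: float
    p: float
    nsim: int


@dataclass
class RankTestResult:
    U: float
    p: float
    r_rb: float
    median_diff: float
    ci_lower: float
    ci_upper: float
    method: str


def resample_slopes(
    t: TrialTable,
    predictor: str = "x_bgbr",
    link: str = "logit",
    B: int = 10_000,
    fraction: float = 0.9,
    seed: int = 0,
    model_predictors: tuple[str, ...] | None = None,
) -> SlopeSample:
    """Subsample-refit distribution of one regression slope.

    Per replicate: draw ``floor(fraction * n)`` rows without replacement,
    refit the full model (default: the single-threshold scenario model),
    and record the coefficient of ``predictor``.  Replicates that fail or
    flag separation are dropped and counted.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if model_predictors is None:
        model_predictors = tuple(
            p for p in SINGLE_THRESHOLD_PREDICTORS if p in t.df.columns
        )
    if predictor not in model_predictors:
        raise ValueError(f"{predictor!r} not in model predictors")
    t.require(["response", *model_predictors])
    y = t.df["response"].to_numpy(dtype=float)
    P = t.df[list(model_predictors)].to_numpy(dtype=float)
    n = len(y)
    m = math.floor(fraction * n)
    k = len(model_predictors) + 1
    if m < k + 2:
        raise ValueError("subsample too small for the model")
    j = 1 + model_predictors.index(predictor)

    rng = np.random.default_rng(seed)
    out = np.empty(B)
    kept = 0
    n_failed = 0
    ones = np.ones(m)
    for _ in range(B):
        idx = rng.choice(n, size=m, replace=False)
        X = np.column_stack([ones, P[idx]])
        try:
            beta, _, _, _, conv = _irls(X, y[idx], link)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        if not conv:
            n_failed += 1
            continue
        out[kept] = beta[j]
        kept += 1
    return SlopeSample(
        values=out[:kept], B=B, fraction=fraction, seed=seed, n_failed=n_failed
    )


def _ks_stat_rows(z: np.ndarray) -> np.ndarray:
    """Row-wise KS statistic of sorted standard-normal CDF values."""
    nsim, n = z.shape
    cdf = stats.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return np.maximum(
        (grid_hi[None, :] - cdf).max(axis=1), (cdf - grid_lo[None, :]).max(axis=1)
    )


def ks_normality_mc(x, nsim: int = 1000, seed: int = 0) -> KSResult:
    """Kolmogorov-Smirnov normality test with a Monte-Carlo null.

    D is computed against Normal(mean(x), sd(x)); the null distribution
    comes from ``nsim`` parametric simulations with parameters
    re-estimated per simulated sample (Lilliefors-style), so the p-value
    p = (1 + #{D_sim >= D_obs}) / (nsim + 1) never reaches zero.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need n >= 5")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance sample")
    d_obs = float(_ks_stat_rows(np.sort((x - mu) / sd)[None, :])[0])
    rng = np.random.default_rng(seed)
    sims = rng.normal(0.0, 1.0, size=(nsim, n))  # location-scale invariant
    z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(
        axis=1, ddof=1, keepdims=True
    )
    d_sim = _ks_stat_rows(np.sort(z, axis=1))
    exceed = int(np.sum(d_sim >= d_obs))
    return KSResult(D=d_obs, p=(1 + exceed) / (nsim + 1), nsim=nsim)


def wilcoxon_rank_sum(
    x, y, ci_B: int = 1000, seed: int = 0
) -> RankTestResult:
    """Two-sample rank-sum test with rank-biserial effect size.

    U counts pairs with x > y (ties half); computed via rank sums in
    O(n log n).  Exact p when n1*n2 <= 400 and no ties, otherwise a
    normal approximation with tie and continuity correction.
    r_rb = 2U/(n1 n2) - 1: +1 means x stochastically larger, -1 smaller.
    The median difference (median(x) - median(y)) carries a percentile
    bootstrap CI over resampled medians.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    U = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 * n2 <= 400 and not has_ties:
        method = "exact"
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    else:
        method = "asymptotic"
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
        )
    r_rb = 2.0 * U / (n1 * n2) - 1.0
    med_diff = float(np.median(x) - np.median(y))
    rng = np.random.default_rng(seed)
    diffs = np.empty(ci_B)
    for b in range(ci_B):
        diffs[b] = np.median(x[rng.integers(0, n1, n1)]) - np.median(
            y[rng.integers(0, n2, n2)]
        )
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return RankTestResult(
        U=U,
        p=p,
        r_rb=float(r_rb),
        median_diff=med_diff,
        ci_lower=float(lo),
        ci_upper=float(hi),
        method=method,
    )
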