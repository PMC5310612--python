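"""AICc-based multimodel inference.

Exhaustive enumeration over predictor subsets, Akaike weights and
evidence ratios, the 1/8 relative-likelihood candidate set, and
zero-method model averaging with adjusted standard errors and relative
importance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometrics import GLMFit, TrialTable, aicc, fit_binomial_glm

__all__ = [
    "MULTIPLE_THRESHOLD_PREDICTORS",
    "SINGLE_THRESHOLD_PREDICTORS",
    "ModelRecord",
    "CandidateSet",
    "AveragedModel",
    "enumerate_models",
    "information_weights",
    "candidate_set",
    "model_average",
]

logger = logging.getLogger(__name__)

#: Scenario models: rejection driven by absolute perceived distance
#: (boundaries on both sides of the own phenotype) ...
MULTIPLE_THRESHOLD_PREDICTORS = ("chromatic_contrast", "achromatic_contrast")
#: ... versus signed position along the colour-gradient axes (one boundary).
SINGLE_THRESHOLD_PREDICTORS = ("x_bgbr", "x_gp", "x_uv", "achromatic_contrast")

# Candidate-set cutoff: relative likelihood >= 1/8, boundary inclusive.
REL_LIKELIHOOD_CUTOFF = 1.0 / 8.0


@dataclass
class ModelRecord:
    predictors: tuple[str, ...]
    fit: GLMFit
    aicc: float
    delta: float = np.nan
    rel_likelihood: float = np.nan
    weight: float = np.nan


@dataclass
class CandidateSet:
    members: list[ModelRecord]
    cutoff: float = REL_LIKELIHOOD_CUTOFF

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty candidate set")
        total = sum(m.weight for m in self.members)
        if abs(total - 1.0) > 1e-12:
            raise ValueError("candidate-set weights must sum to 1")


@dataclass
class AveragedModel:
    """Zero-method averaged coefficients with adjusted SEs and importance."""

    estimates: dict[str, float]
    adjusted_se: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    z: dict[str, float]
    importance: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.estimates:
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.estimates[name],
                    "se_adjusted": self.adjusted_se[name],
                    "LCL": self.ci_lower[name],
                    "UCL": self.ci_upper[name],
                    "z": self.z[name],
                    "importance": self.importance.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def enumerate_models(
    global_predictors: list[str], t: TrialTable, link: str = "logit"
) -> list[ModelRecord]:
    """Fit all 2^p predictor subsets (intercept always included).

    Non-converged models are kept but logged; records are returned sorted
    by AICc ascending, ties broken by subset lexicographic order, with
    delta / relative likelihood / weight computed over the full set.
    """
    p = len(global_predictors)
    if p > 12:
        raise ValueError("exhaustive enumeration too large (p > 12)")
    records: list[ModelRecord] = []
    import warnings as _warnings

    for r in range(p + 1):
        for subset in itertools.combinations(global_predictors, r):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                fit = fit_binomial_glm(t, list(subset), link)
            if not fit.converged:
                logger.info("model %s flagged (possible separation)", subset)
            records.append(
                ModelRecord(
                    predictors=subset,
                    fit=fit,
                    aicc=aicc(fit.loglik, fit.k, fit.n),
                )
            )
    records.sort(key=lambda m: (m.aicc, m.predictors))
    info = information_weights([m.aicc for m in records])
    for m, d, rl, w in zip(
        records, info["delta"], info["rel_likelihood"], info["weight"]
    ):
        m.delta, m.rel_likelihood, m.weight = float(d), float(rl), float(w)
    return records


def information_weights(aicc_values) -> dict:
    """Akaike deltas, relative likelihoods, weights and evidence ratios.

    weight_i = exp(-delta_i/2) / sum_j exp(-delta_j/2);
    ER(i, j) = weight_i / weight_j = exp((aicc_j - aicc_i)/2).
    """
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 AICc values")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite AICc value")
    delta = a - a.min()
    rel = np.exp(-delta / 2.0)
    weight = rel / rel.sum()
    er = np.exp((a[None, :] - a[:, None]) / 2.0)
    return {
        "delta": delta,
        "rel_likelihood": rel,
        "weight": weight,
        "evidence_ratio": er,
    }


def candidate_set(models: list[ModelRecord]) -> CandidateSet:
    """Keep models with relative likelihood >= 1/8 of the best; renormalize.

    Equivalent to delta <= 2 ln 8; the boundary is inclusive.
    """
    if not models:
        raise ValueError("empty model list")
    best = min(m.aicc for m in models)
    kept = [
        m
        for m in models
        if np.exp(-(m.aicc - best) / 2.0) >= REL_LIKELIHOOD_CUTOFF - 1e-15
    ]
    kept.sort(key=lambda m: (m.aicc, m.predictors))
    rel = np.array([np.exp(-(m.aicc - best) / 2.0) for m in kept])
    w = rel / rel.sum()
    out = []
    for m, d, rl, wi in zip(kept, [m.aicc - best for m in kept], rel, w):
        out.append(
            ModelRecord(
                predictors=m.predictors,
                fit=m.fit,
                aicc=m.aicc,
                delta=float(d),
                rel_likelihood=float(rl),
                weight=float(wi),
            )
        )
    return CandidateSet(members=out)


def model_average(
    cs: CandidateSet, global_predictors: list[str] | None = None
) -> AveragedModel:
    """Zero-method average over the candidate set.

    A predictor's coefficient (and SE) counts as 0 in models that exclude
    it, shrinking averaged effects toward zero.  Adjusted SE per term:
    sum_i w_i * sqrt(se_i^2 + (b_i - b_bar)^2).  Importance is the summed
    weight of models containing the term (1 for the intercept).  Passing
    ``global_predictors`` reports terms absent from every candidate model
    as estimate 0, importance 0.
    """
    all_preds = list(global_predictors) if global_predictors else []
    for m in cs.members:
        for p in m.predictors:
            if p not in all_preds:
                all_preds.append(p)
    names = ["(intercept)", *all_preds]

    est: dict[str, float] = {}
    se_adj: dict[str, float] = {}
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    zval: dict[str, float] = {}
    imp: dict[str, float] = {}

    for name in names:
        betas, ses, ws = [], [], []
        importance = 0.0
        for m in cs.members:
            w = m.weight
            if name == "(intercept)":
                j = 0
                present = True
            else:
                present = name in m.predictors
                j = 1 + m.predictors.index(name) if present else -1
            if present:
                betas.append(m.fit.beta[j])
                ses.append(m.fit.se[j])
                importance += w
            else:
                betas.append(0.0)
                ses.append(0.0)
            ws.append(w)
        betas = np.asarray(betas)
        ses = np.asarray(ses)
        ws = np.asarray(ws)
        b_bar = float(np.sum(ws * betas))
        se_bar = float(np.sum(ws * np.sqrt(ses**2 + (betas - b_bar) ** 2)))
        est[name] = b_bar
        se_adj[name] = se_bar
        lo[name] = b_bar - 1.96 * se_bar
        hi[name] = b_bar + 1.96 * se_bar
        zval[name] = b_bar / se_bar if se_bar > 0 else np.nan
        if name != "(intercept)":
            imp[name] = importance
    return AveragedModel(
        estimates=est,
        adjusted_se=se_adj,
        ci_lower=lo,
        ci_upper=hi,
        z=zval,
        importance=imp,
    )
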