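"""Classical (frequentist) pairwise meta-analysis with heterogeneity.

Implements inverse-variance fixed-effect pooling, DerSimonian-Laird
random-effects pooling, Cochran's Q with its chi-square test, the I²
statistic with the moderate (>=50%) / considerable (>=70%) classification,
between-drug subgroup heterogeneity, and leave-studies-out sensitivity
re-pooling. These reproduce the "classical analysis" half of a drug-vs-
placebo comparison table and the tabular content of per-outcome forest
plots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    EffectEstimate,
    EvidenceNetwork,
    FractureOutcome,
    network_effects,
)

logger = logging.getLogger(__name__)

CLASS_NONE = "none/low"
CLASS_MODERATE = "moderate"
CLASS_CONSIDERABLE = "considerable"


def classify_heterogeneity(i_squared: float) -> str:
    """Classify an I² percentage: >=50% moderate, >=70% considerable.

    The cut points follow the usual systematic-review convention; values
    exactly on a boundary take the higher class.
    """
    if not 0.0 <= i_squared <= 100.0:
        raise ValueError(f"I² must lie in [0, 100], got {i_squared}")
    if i_squared >= 70.0:
        return CLASS_CONSIDERABLE
    if i_squared >= 50.0:
        return CLASS_MODERATE
    return CLASS_NONE


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q, its test, I² and the DerSimonian-Laird tau²."""

    q: float
    df: int
    p_value: float
    i_squared: float  # percent
    tau_squared: float
    classification: str

    @classmethod
    def from_q(cls, q: float, df: int, tau_squared: float) -> "HeterogeneityResult":
        i2 = 0.0 if q <= 0 else max(0.0, 100.0 * (q - df) / q)
        p = 1.0 if df <= 0 else float(stats.chi2.sf(q, df))
        return cls(q=q, df=df, p_value=p, i_squared=i2,
                   tau_squared=tau_squared, classification=classify_heterogeneity(i2))


def _check_estimates(estimates: Sequence[EffectEstimate]) -> None:
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty collection of estimates")


def pool_fixed(estimates: Iterable[EffectEstimate]) -> EffectEstimate:
    """Inverse-variance fixed-effect pooled log odds ratio.

    Weights are 1/se²; the pooled standard error is 1/sqrt(sum of weights),
    so the pooled se never exceeds the smallest input se.
    """
    estimates = list(estimates)
    _check_estimates(estimates)
    w = np.array([1.0 / e.se**2 for e in estimates])
    y = np.array([e.log_or for e in estimates])
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    first = estimates[0]
    return EffectEstimate(
        log_or=pooled, se=se, method="fixed",
        drug=first.drug if len({e.drug for e in estimates}) == 1 else None,
        outcome=first.outcome if len({e.outcome for e in estimates}) == 1 else None,
        p_value=2.0 * float(stats.norm.sf(abs(pooled / se))),
    )


def cochran_q(estimates: Sequence[EffectEstimate]) -> tuple[float, int]:
    """Cochran's Q about the fixed-effect mean, with its degrees of freedom."""
    _check_estimates(estimates)
    w = np.array([1.0 / e.se**2 for e in estimates])
    y = np.array([e.log_or for e in estimates])
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2)), len(estimates) - 1


def heterogeneity(estimates: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Q, I² and DerSimonian-Laird tau² for a set of study estimates."""
    estimates = list(estimates)
    q, df = cochran_q(estimates)
    w = np.array([1.0 / e.se**2 for e in estimates])
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = 0.0 if denom <= 0 else max(0.0, (q - df) / denom)
    return HeterogeneityResult.from_q(q=q, df=df, tau_squared=tau2)


def pool_random(
    estimates: Iterable[EffectEstimate],
) -> tuple[EffectEstimate, HeterogeneityResult]:
    """DerSimonian-Laird random-effects pooling.

    tau² = max(0, (Q - df) / (sum w - sum w² / sum w)) with fixed-effect
    weights in Q; the pooled estimate then uses weights 1/(se² + tau²).
    With a single estimate the method falls back to fixed-effect pooling
    with a warning.
    """
    estimates = list(estimates)
    _check_estimates(estimates)
    if len(estimates) == 1:
        logger.warning("random-effects pooling of a single estimate: "
                       "falling back to fixed effect")
        est = pool_fixed(estimates)
        return est.retagged("random"), HeterogeneityResult.from_q(0.0, 0, 0.0)
    het = heterogeneity(estimates)
    w = np.array([1.0 / (e.se**2 + het.tau_squared) for e in estimates])
    y = np.array([e.log_or for e in estimates])
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    first = estimates[0]
    est = EffectEstimate(
        log_or=pooled, se=se, method="random",
        drug=first.drug if len({e.drug for e in estimates}) == 1 else None,
        outcome=first.outcome if len({e.outcome for e in estimates}) == 1 else None,
        p_value=2.0 * float(stats.norm.sf(abs(pooled / se))),
    )
    return est, het


def pool_by_drug(
    network: EvidenceNetwork,
    method: str = "fixed",
    correction: float = 0.5,
) -> dict[str, EffectEstimate]:
    """Per-drug pooled drug-vs-placebo estimates for one outcome's network."""
    if method not in ("fixed", "random"):
        raise ValueError("method must be 'fixed' or 'random'")
    effects = network_effects(network, correction=correction)
    out: dict[str, EffectEstimate] = {}
    for drug in network.drugs:
        per_drug = [e for e in effects if e.drug == drug]
        if not per_drug:
            continue
        if method == "fixed" or len(per_drug) == 1:
            out[drug] = pool_fixed(per_drug).retagged(method)
        else:
            out[drug], _ = pool_random(per_drug)
    return out


def pool_all_drugs(
    network: EvidenceNetwork, method: str = "fixed", correction: float = 0.5
) -> EffectEstimate:
    """Pool every study in the network into one all-drugs-vs-placebo estimate."""
    effects = network_effects(network, correction=correction)
    if method == "random":
        return pool_random(effects)[0]
    return pool_fixed(effects)


def subgroup_heterogeneity(
    per_drug: Mapping[str, EffectEstimate],
) -> HeterogeneityResult:
    """Between-drug heterogeneity of the per-drug pooled estimates.

    Cochran's Q applied to the pooled per-drug estimates around the overall
    fixed-effect mean, with df = number of drugs - 1. Answers whether drug
    classes differ more than their within-drug sampling error allows.
    """
    if len(per_drug) < 2:
        raise ValueError("between-drug heterogeneity needs >= 2 drugs")
    return heterogeneity(list(per_drug.values()))


@dataclass(frozen=True)
class SensitivityResult:
    """Re-pooled estimate with heterogeneity before and after exclusions."""

    estimate: EffectEstimate
    before: HeterogeneityResult
    after: HeterogeneityResult

    @property
    def i_squared_drop(self) -> float:
        return self.before.i_squared - self.after.i_squared


def sensitivity_subset(
    network: EvidenceNetwork,
    excluded_study_ids: Iterable[str],
    correction: float = 0.5,
) -> SensitivityResult:
    """Random-effects re-pooling after excluding the listed studies."""
    before = heterogeneity(network_effects(network, correction=correction))
    excluded = set(excluded_study_ids)
    subset = network.subset(excluded) if excluded else network
    est, after = pool_random(network_effects(subset, correction=correction))
    return SensitivityResult(estimate=est, before=before, after=after)


def forest_data(
    network: EvidenceNetwork, method: str = "fixed", correction: float = 0.5
) -> pd.DataFrame:
    """Tabular forest-plot content: per-study rows plus pooled rows.

    Columns: drug, study_id, or, ci_low, ci_high, weight_pct, row_type.
    Weights are the outcome-wide inverse-variance weights (in percent);
    pooled rows carry the per-drug and all-drugs pooled estimates.
    """
    effects = network_effects(network, correction=correction)
    total_w = sum(1.0 / e.se**2 for e in effects)
    rows = []
    for e in effects:
        rows.append({
            "drug": e.drug, "study_id": e.study_id, "or": e.or_value,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "weight_pct": 100.0 / e.se**2 / total_w, "row_type": "study",
        })
    for drug, est in pool_by_drug(network, method=method, correction=correction).items():
        rows.append({
            "drug": drug, "study_id": None, "or": est.or_value,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "weight_pct": None, "row_type": "pooled_drug",
        })
    overall = pool_all_drugs(network, method=method, correction=correction)
    rows.append({
        "drug": "all_drugs", "study_id": None, "or": overall.or_value,
        "ci_low": overall.ci_low, "ci_high": overall.ci_high,
        "weight_pct": None, "row_type": "pooled_all",
    })
    return pd.DataFrame(rows)
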