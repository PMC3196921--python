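"""Random-effects meta-regression of study log odds ratios on drug
indicators and baseline covariates.

Model: for study i with log-OR y_i, within-study variance se_i² and design
row x_i (intercept + drug dummies + selected covariates),

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau²),  e_i ~ N(0, se_i²),

with tau² estimated by REML (default) or by the DerSimonian-Laird-style
method of moments, and beta by weighted least squares at the tau² estimate.
Confidence intervals use normal theory. Studies missing any selected
covariate are listwise-deleted with a log message.

The adjustment question this answers: do differences in baseline age, hip
BMD or prior-fracture prevalence across trials, rather than the drugs
themselves, drive the between-trial variation in effect? With many drug
dummies and few studies the design readily becomes collinear, which shows
up as exploded confidence intervals; :func:`collinearity_check` detects
this via interval-width ratios and the design condition number.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data import EffectEstimate, EvidenceNetwork, network_effects

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ("mean_age", "bmd_hip", "prior_vert_fracture_pct",
                   "years_since_menopause", "followup")

CONDITION_NUMBER_LIMIT = 1e3
CI_EXPLOSION_RATIO = 10.0


class InsufficientStudiesError(ValueError):
    """Raised when residual degrees of freedom are exhausted — the analysis'
    own failure mode when covariates are added to a sparse network."""


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


@dataclass
class MetaRegressionResult:
    coefficients: dict[str, Coefficient]
    tau_squared: float
    n_studies: int
    condition_number: float
    collinearity_flags: dict[str, bool]
    reference_drug: str | None
    dropped_studies: tuple[str, ...]
    terms: tuple[str, ...]

    def coefficient(self, term: str) -> Coefficient:
        return self.coefficients[term]


def _design_matrix(
    effects: Sequence[EffectEstimate],
    network: EvidenceNetwork,
    covariates: Sequence[str],
    reference_drug: str | None,
):
    by_id = {s.study_id: s for s in network.studies}
    drugs = sorted({e.drug for e in effects})
    if reference_drug is None:
        reference_drug = drugs[0]
    elif reference_drug not in drugs:
        raise ValueError(f"reference drug {reference_drug!r} not in network")
    dummy_drugs = [d for d in drugs if d != reference_drug]
    kept, dropped = [], []
    rows, y, v = [], [], []
    for e in effects:
        study = by_id[e.study_id]
        cov_values = [study.covariates.get(c) for c in covariates]
        if any(val is None for val in cov_values):
            dropped.append(e.study_id)
            continue
        row = [1.0]
        row += [1.0 if e.drug == d else 0.0 for d in dummy_drugs]
        row += [float(val) for val in cov_values]
        rows.append(row)
        y.append(e.log_or)
        v.append(e.se**2)
        kept.append(e.study_id)
    if dropped:
        logger.info("meta-regression dropped %d studies with missing "
                    "covariates: %s", len(dropped), dropped)
    terms = ["intercept"] + [f"drug[{d}]" for d in dummy_drugs] + list(covariates)
    return (np.array(rows), np.array(y), np.array(v), terms,
            reference_drug, tuple(dropped))


def _neg_restricted_loglik(tau2: float, X: np.ndarray, y: np.ndarray,
                           v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    Xtw = X.T * w
    xtwx = Xtw @ X
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtwx, Xtw @ y)
    resid = y - X @ beta
    return 0.5 * (
        -np.sum(np.log(w)) + logdet_xtwx + float(np.sum(w * resid**2))
    )


def _tau2_mom(X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments tau² generalizing DerSimonian-Laird to regression."""
    w = 1.0 / v
    Xtw = X.T * w
    beta = np.linalg.solve(Xtw @ X, Xtw @ y)
    resid = y - X @ beta
    q_e = float(np.sum(w * resid**2))
    n, p = X.shape
    # trace of P = W - W X (X'WX)^-1 X' W
    wx = (X.T * w).T
    trace_p = float(np.sum(w) - np.trace(np.linalg.solve(Xtw @ X, wx.T @ wx)))
    if trace_p <= 0:
        return 0.0
    return max(0.0, (q_e - (n - p)) / trace_p)


def fit_metareg(
    network: EvidenceNetwork,
    covariates: Sequence[str] = (),
    tau2_method: str = "reml",
    reference_drug: str | None = None,
    correction: float = 0.5,
) -> MetaRegressionResult:
    """Fit the random-effects meta-regression on one outcome's network.

    ``covariates`` are study-covariate names (subset of
    :data:`COVARIATE_NAMES`); drug dummies relative to ``reference_drug``
    (first alphabetically by default) are always included, so the intercept
    is the reference drug's effect.
    """
    unknown = set(covariates) - set(COVARIATE_NAMES)
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    if tau2_method not in ("reml", "mom"):
        raise ValueError("tau2_method must be 'reml' or 'mom'")
    effects = network_effects(network, correction=correction)
    X, y, v, terms, reference_drug, dropped = _design_matrix(
        effects, network, covariates, reference_drug
    )
    n, p = X.shape if X.ndim == 2 and len(X) else (0, len(terms))
    if n <= p:
        raise InsufficientStudiesError(
            f"not enough studies for the analysis: {n} studies for {p} "
            "design terms leaves no residual degrees of freedom"
        )
    if tau2_method == "mom":
        tau2 = _tau2_mom(X, y, v)
    else:
        upper = max(10.0 * float(np.var(y)), 1.0)
        res = optimize.minimize_scalar(
            _neg_restricted_loglik, bounds=(0.0, upper), args=(X, y, v),
            method="bounded", options={"xatol": 1e-10},
        )
        tau2 = float(res.x)
        if _neg_restricted_loglik(0.0, X, y, v) <= res.fun:
            tau2 = 0.0
    w = 1.0 / (v + tau2)
    Xtw = X.T * w
    xtwx_inv = np.linalg.inv(Xtw @ X)
    beta = xtwx_inv @ (Xtw @ y)
    se = np.sqrt(np.diag(xtwx_inv))
    coefficients = {}
    for j, term in enumerate(terms):
        z = beta[j] / se[j]
        coefficients[term] = Coefficient(
            estimate=float(beta[j]), se=float(se[j]),
            ci_low=float(beta[j] - 1.96 * se[j]),
            ci_high=float(beta[j] + 1.96 * se[j]),
            p_value=2.0 * float(stats.norm.sf(abs(z))),
        )
    # condition number of the weighted design with unit-norm columns
    scaled = X * np.sqrt(w)[:, None]
    norms = np.linalg.norm(scaled, axis=0)
    norms[norms == 0] = 1.0
    cond = float(np.linalg.cond(scaled / norms))
    result = MetaRegressionResult(
        coefficients=coefficients, tau_squared=tau2, n_studies=n,
        condition_number=cond, collinearity_flags={},
        reference_drug=reference_drug, dropped_studies=dropped,
        terms=tuple(terms),
    )
    result.collinearity_flags = collinearity_check(result, _design=(scaled / norms))
    return result


def collinearity_check(
    result: MetaRegressionResult,
    unadjusted_widths: Mapping[str, float] | None = None,
    ratio: float = CI_EXPLOSION_RATIO,
    _design: np.ndarray | None = None,
) -> dict[str, bool]:
    """Flag terms whose confidence intervals have exploded.

    A term is flagged when its CI width exceeds ``ratio`` times a reference
    width (the drug's unadjusted pooled CI width when supplied, else the
    median term width), or when the design condition number exceeds 10³ and
    the term loads on a near-null singular direction of the design.
    """
    flags = {term: False for term in result.terms}
    widths = {t: c.ci_width for t, c in result.coefficients.items()}
    finite = [w for w in widths.values() if math.isfinite(w)]
    median_width = float(np.median(finite)) if finite else float("nan")
    for term, width in widths.items():
        if term == "intercept":
            continue
        reference = None
        if unadjusted_widths is not None and term.startswith("drug["):
            drug = term[5:-1]
            reference = unadjusted_widths.get(drug)
        if reference is None:
            reference = median_width
        if reference and math.isfinite(reference) and width > ratio * reference:
            flags[term] = True
    if result.condition_number > CONDITION_NUMBER_LIMIT and _design is not None:
        _, svals, vt = np.linalg.svd(_design, full_matrices=False)
        null_dirs = vt[svals < svals[0] / CONDITION_NUMBER_LIMIT]
        for direction in null_dirs:
            for j, term in enumerate(result.terms):
                if abs(direction[j]) > 0.1:
                    flags[term] = True
    return flags


def unadjusted_drug_ci_widths(
    per_drug: Mapping[str, EffectEstimate]
) -> dict[str, float]:
    """Log-scale CI widths of unadjusted per-drug pooled estimates, for use
    as the reference in :func:`collinearity_check`."""
    return {drug: 2 * 1.96 * est.se for drug, est in per_drug.items()}
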