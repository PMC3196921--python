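"""League tables, numbers needed to treat, classical-vs-Bayesian consistency
and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import logging
import math
import platform
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import __version__
from .bayes import (
    MCMCConfig,
    PosteriorSummary,
    pairwise_contrasts,
    run_mcmc,
    summarize_posteriors,
)
from .diagnostics import diagnostics as diagnostics_report
from .bucher import bucher_league_table
from .classical import (
    forest_data,
    heterogeneity,
    pool_all_drugs,
    pool_by_drug,
    subgroup_heterogeneity,
)
from .data import (
    EffectEstimate,
    EvidenceNetwork,
    FractureOutcome,
    network_effects,
    read_network_csv,
)
from .metareg import InsufficientStudiesError, fit_metareg

logger = logging.getLogger(__name__)

CONSISTENCY_THRESHOLD = 0.01  # "agrees to the second decimal place"


def nnt(or_ac: float, baseline_risk: float) -> float | None:
    """Number needed to treat with A instead of comparator C.

    The comparator risk is ``baseline_risk``; the risk under A applies the
    odds ratio on the odds scale, risk_A = expit(logit(baseline) + ln OR);
    NNT = 1 / (risk_C - risk_A). Negative values mean the comparator is
    favoured; OR = 1 has no risk difference and returns None (reported NR).
    """
    if not 0.0 < baseline_risk < 1.0:
        raise ValueError(f"baseline risk must be in (0, 1), got {baseline_risk}")
    if or_ac <= 0:
        raise ValueError("odds ratio must be > 0")
    if or_ac == 1.0:
        return None
    risk_a = float(expit(logit(baseline_risk) + math.log(or_ac)))
    return 1.0 / (baseline_risk - risk_a)


@dataclass(frozen=True)
class ConsistencyRow:
    drug: str
    classical_or: float
    bayesian_or: float
    significant: bool

    @property
    def abs_difference(self) -> float:
        return abs(self.classical_or - self.bayesian_or)

    @property
    def agrees(self) -> bool:
        return self.abs_difference <= CONSISTENCY_THRESHOLD


@dataclass
class ConsistencyReport:
    """Per-drug agreement between classical pooled and Bayesian posterior ORs.

    ``passed`` applies the second-decimal rule (absolute OR difference at
    most 0.01) to the statistically significant drug effects, mirroring how
    robustness of an indirect comparison is argued: the two methodologies
    must tell the same story wherever the data speak clearly.
    """

    rows: list[ConsistencyRow]
    passed: bool
    max_abs_difference: float
    max_abs_difference_significant: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"drug": r.drug, "classical_or": r.classical_or,
             "bayesian_or": r.bayesian_or, "abs_difference": r.abs_difference,
             "significant": r.significant, "agrees": r.agrees}
            for r in self.rows
        ])


def consistency_report(
    classical: Mapping[str, EffectEstimate],
    bayesian: Mapping[str, PosteriorSummary],
) -> ConsistencyReport:
    """Compare classical pooled ORs with Bayesian posterior mean ORs."""
    if set(classical) != set(bayesian):
        only_c = sorted(set(classical) - set(bayesian))
        only_b = sorted(set(bayesian) - set(classical))
        raise ValueError(
            f"drug sets differ: classical-only {only_c}, bayesian-only {only_b}"
        )
    rows = []
    for drug in sorted(classical):
        c, b = classical[drug], bayesian[drug]
        rows.append(ConsistencyRow(
            drug=drug, classical_or=c.or_value, bayesian_or=b.or_mean,
            significant=c.significant and b.significant,
        ))
    sig = [r.abs_difference for r in rows if r.significant]
    return ConsistencyReport(
        rows=rows,
        passed=all(r.agrees for r in rows if r.significant),
        max_abs_difference=max(r.abs_difference for r in rows),
        max_abs_difference_significant=max(sig) if sig else None,
    )


# display-precision conventions of the summary tables
def round_or(x: float) -> float:
    return round(x, 2)


def round_prob(x: float) -> float:
    return round(x, 2)


def round_effect_size(x: float) -> float:
    return round(x, 1)


def round_nnt(x: float | None) -> int | None:
    return None if x is None else int(round(x))


def posterior_table(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    """Drug-vs-placebo posterior table: OR (95% CrI), probability-best,
    effect size — rounded to display precision."""
    return pd.DataFrame([
        {"drug": s.drug, "or": round_or(s.or_mean),
         "cri_low": round_or(s.cri_low), "cri_high": round_or(s.cri_high),
         "prob_best": round_prob(s.prob_best),
         "effect_size": round_effect_size(s.effect_size)}
        for s in summaries
    ])


def run_pipeline(
    data_path,
    out_dir,
    outcomes: Sequence[FractureOutcome | str],
    mcmc: MCMCConfig | None = None,
    covariates: Sequence[str] = (),
    pooling: str = "fixed",
    nnt_baseline_risk: float | None = None,
    correction: float = 0.5,
) -> dict:
    """Execute the full analysis for each outcome and write an artifact bundle.

    Stages per outcome: classical per-drug pooling with heterogeneity and
    forest-data export, Bucher league table, Bayesian posterior run with
    diagnostics, optional meta-regression, and the classical-vs-Bayesian
    consistency report. Outputs are CSV/JSON under ``out_dir`` plus a run
    log recording the seed and software versions. Any stage failure aborts
    with the stage name; partially written outputs are removed. Idempotent
    for a fixed seed.
    """
    if not outcomes:
        raise ValueError("no outcomes selected")
    outcomes = [FractureOutcome(o) for o in outcomes]
    mcmc = mcmc or MCMCConfig()
    out_dir = Path(out_dir)
    staging = out_dir.with_name(out_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    stage = "setup"
    try:
        bundle: dict = {"outcomes": {}}
        for outcome in outcomes:
            odir = staging / outcome.value
            odir.mkdir()
            stage = f"{outcome.value}:load"
            network = read_network_csv(data_path, outcome)
            baseline = nnt_baseline_risk
            if baseline is None:
                # pooled placebo event rate across the outcome's trials
                ev = sum(s.placebo_arm.events for s in network.studies)
                tot = sum(s.placebo_arm.total for s in network.studies)
                baseline = ev / tot
            stage = f"{outcome.value}:classical"
            per_drug = pool_by_drug(network, method=pooling, correction=correction)
            overall = pool_all_drugs(network, method=pooling, correction=correction)
            het_all = heterogeneity(network_effects(network, correction=correction))
            het_between = (
                subgroup_heterogeneity(per_drug) if len(per_drug) > 1 else None
            )
            forest_data(network, method=pooling, correction=correction).to_csv(
                odir / "forest.csv", index=False
            )
            stage = f"{outcome.value}:bucher"
            bucher_lt = bucher_league_table(
                per_drug, outcome=outcome, nnt_baseline_risk=baseline
            )
            bucher_lt.to_csv(odir / "bucher_league.csv")
            stage = f"{outcome.value}:bayes"
            draws = run_mcmc(network, mcmc)
            summaries = summarize_posteriors(draws)
            posterior_table(summaries).to_csv(odir / "posterior_drugs.csv",
                                              index=False)
            bayes_lt = pairwise_contrasts(draws, nnt_baseline_risk=baseline)
            bayes_lt.to_csv(odir / "bayes_league.csv")
            diag = diagnostics_report(draws)
            (odir / "diagnostics.json").write_text(
                json.dumps(diag.to_dict(), indent=2, default=float)
            )
            stage = f"{outcome.value}:metareg"
            metareg_summary = None
            if covariates or len(per_drug) > 1:
                try:
                    fit = fit_metareg(network, covariates=covariates,
                                      correction=correction)
                    coef_rows = [
                        {"term": t, "estimate": c.estimate, "se": c.se,
                         "ci_low": c.ci_low, "ci_high": c.ci_high,
                         "p_value": c.p_value,
                         "collinear": fit.collinearity_flags[t]}
                        for t, c in fit.coefficients.items()
                    ]
                    pd.DataFrame(coef_rows).to_csv(odir / "metareg.csv",
                                                   index=False)
                    metareg_summary = {
                        "tau_squared": fit.tau_squared,
                        "n_studies": fit.n_studies,
                        "condition_number": fit.condition_number,
                        "collinear_terms": [
                            t for t, f in fit.collinearity_flags.items() if f
                        ],
                    }
                except InsufficientStudiesError as err:
                    metareg_summary = {"error": str(err)}
                    logger.warning("%s meta-regression skipped: %s",
                                   outcome.value, err)
            stage = f"{outcome.value}:consistency"
            report = consistency_report(
                per_drug, {s.drug: s for s in summaries}
            )
            report.to_frame().to_csv(odir / "consistency.csv", index=False)
            bundle["outcomes"][outcome.value] = {
                "n_studies": network.n_studies,
                "drugs": list(network.drugs),
                "baseline_risk": baseline,
                "overall_or": overall.or_value,
                "i_squared_all": het_all.i_squared,
                "i_squared_between_drugs":
                    het_between.i_squared if het_between else None,
                "consistency_pass": report.passed,
                "diagnostics_pass": diag.overall_pass,
                "metareg": metareg_summary,
            }
        bundle["run_log"] = {
            "seed": mcmc.seed,
            "chains": mcmc.chains,
            "iterations": mcmc.iterations,
            "burn_in": mcmc.burn_in,
            "starnma_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        }
        (staging / "summary.json").write_text(
            json.dumps(bundle, indent=2, default=float)
        )
    except Exception as err:
        shutil.rmtree(staging, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
    return bundle
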