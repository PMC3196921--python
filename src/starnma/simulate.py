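"""Synthetic star-shaped trial networks with known ground truth.

Every downstream method in this package (classical pooling, Bucher indirect
comparisons, Bayesian network meta-analysis, meta-regression) is exercised
against networks generated here, because the raw arm counts behind published
nine-drug osteoporosis comparisons are not public. The generative model is
the fixed/random-effect binomial-logit model the analyses assume:

* study i of drug t draws a baseline (placebo) logit
  ``mu_i ~ Normal(baseline_logit_mean, baseline_logit_sd^2)``,
* a study-level drug effect
  ``delta_i ~ Normal(d_t + covariate terms, tau^2)`` on the log-OR scale,
* arm counts ``r ~ Binomial(n, expit(mu_i))`` (placebo) and
  ``Binomial(n, expit(mu_i + delta_i))`` (drug).

``tau = 0`` is the fixed-effect world. Optional covariate slopes make the
study-level effect depend linearly on baseline age, hip BMD and prior
vertebral-fracture prevalence (centred at the midpoints of the published
covariate ranges so the average effect stays ``d_t``), which makes
meta-regression slope recovery a well-posed exercise.

Reproducibility: one master seed; each (drug, study index) gets its own
deterministic substream, so adding a drug to a scenario does not perturb any
other drug's simulated trials.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.special import expit, logit

from .data import (
    ArmCount,
    EffectEstimate,
    EvidenceNetwork,
    FractureOutcome,
    LeagueCell,
    LeagueTable,
    StudyCovariates,
    TwoArmStudy,
)

# published covariate ranges across included trials (uniform sampling ranges)
AGE_RANGE = (51.2, 78.0)            # years
YSM_RANGE = (2.7, 43.7)             # years since menopause
BMD_RANGE = (0.25, 1.08)            # hip BMD, g/cm^2
PRIOR_FX_RANGE = (0.0, 100.0)       # % with prior vertebral fracture
FOLLOWUP_RANGE = (1.0, 4.0)         # years

# logits beyond this magnitude round to risk 0/1 in float64
_LOGIT_LIMIT = 36.0


@dataclass(frozen=True)
class CovariateModel:
    """Linear effect modification of the study-level log-OR.

    Slopes are per year of age, per g/cm^2 of hip BMD and per percentage
    point of prior vertebral fracture prevalence, applied to covariates
    centred at the midpoints of their published ranges.
    """

    age_slope: float = 0.0
    bmd_slope: float = 0.0
    prior_fx_slope: float = 0.0

    def shift(self, cov: StudyCovariates) -> float:
        shift = 0.0
        if self.age_slope and cov.mean_age is not None:
            shift += self.age_slope * (cov.mean_age - _mid(AGE_RANGE))
        if self.bmd_slope and cov.bmd_hip is not None:
            shift += self.bmd_slope * (cov.bmd_hip - _mid(BMD_RANGE))
        if self.prior_fx_slope and cov.prior_vert_fracture_pct is not None:
            shift += self.prior_fx_slope * (
                cov.prior_vert_fracture_pct - _mid(PRIOR_FX_RANGE)
            )
        return shift

    def max_abs_shift(self) -> float:
        return (
            abs(self.age_slope) * (AGE_RANGE[1] - AGE_RANGE[0]) / 2
            + abs(self.bmd_slope) * (BMD_RANGE[1] - BMD_RANGE[0]) / 2
            + abs(self.prior_fx_slope) * (PRIOR_FX_RANGE[1] - PRIOR_FX_RANGE[0]) / 2
        )


def _mid(rng: tuple[float, float]) -> float:
    return 0.5 * (rng[0] + rng[1])


@dataclass(frozen=True)
class SyntheticConfig:
    """Scenario description for one outcome's synthetic evidence network."""

    true_log_or: Mapping[str, float]
    baseline_logit_mean: float
    baseline_logit_sd: float = 0.0
    tau: float = 0.0
    studies_per_drug: Mapping[str, int] = field(default_factory=dict)
    arm_size: int | Mapping[str, int] = 1000
    covariate_model: CovariateModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_logit_sd < 0 or self.tau < 0:
            raise ValueError("baseline_logit_sd and tau must be >= 0")
        spd = dict(self.studies_per_drug) or {d: 1 for d in self.true_log_or}
        unknown = set(spd) - set(self.true_log_or)
        if unknown:
            raise ValueError(f"studies_per_drug for unknown drugs: {sorted(unknown)}")
        if any(k < 1 for k in spd.values()):
            raise ValueError("studies_per_drug counts must be >= 1")
        for drug in self.true_log_or:
            if self._arm_size(drug) < 10:
                raise ValueError("arm sizes must be >= 10")
        object.__setattr__(self, "studies_per_drug", spd)
        # risk must stay inside (0,1) in float even 6 SD out
        worst = (
            abs(self.baseline_logit_mean)
            + 6.0 * self.baseline_logit_sd
            + max((abs(v) for v in self.true_log_or.values()), default=0.0)
            + 6.0 * self.tau
            + (self.covariate_model.max_abs_shift() if self.covariate_model else 0.0)
        )
        if worst > _LOGIT_LIMIT:
            raise ValueError(
                f"configuration reaches logit magnitude {worst:.1f} at 6 SD; "
                "event risks would degenerate to 0 or 1"
            )

    def _arm_size(self, drug: str) -> int:
        if isinstance(self.arm_size, Mapping):
            return int(self.arm_size[drug])
        return int(self.arm_size)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.true_log_or))


def _study_rng(seed: int, drug: str, index: int) -> np.random.Generator:
    """Deterministic per-study substream keyed by (seed, drug, study index)."""
    drug_key = zlib.crc32(drug.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, drug_key, index]))


def generate_network(
    config: SyntheticConfig, outcome: FractureOutcome | str
) -> EvidenceNetwork:
    """Simulate a star-shaped evidence network under the scenario.

    Deterministic for a fixed config (including the seed); per-drug
    substreams make the draw for one drug independent of which other drugs
    are present.
    """
    outcome = FractureOutcome(outcome)
    studies: list[TwoArmStudy] = []
    for drug in config.drugs:
        d_t = config.true_log_or[drug]
        n = config._arm_size(drug)
        for j in range(config.studies_per_drug[drug]):
            rng = _study_rng(config.seed, drug, j)
            covariates = StudyCovariates(
                mean_age=round(rng.uniform(*AGE_RANGE), 1),
                years_since_menopause=round(rng.uniform(*YSM_RANGE), 1),
                bmd_hip=round(rng.uniform(*BMD_RANGE), 2),
                prior_vert_fracture_pct=round(rng.uniform(*PRIOR_FX_RANGE), 1),
                followup=round(rng.uniform(*FOLLOWUP_RANGE), 1),
            )
            mu = rng.normal(config.baseline_logit_mean, config.baseline_logit_sd)
            mean_delta = d_t
            if config.covariate_model is not None:
                mean_delta += config.covariate_model.shift(covariates)
            delta = rng.normal(mean_delta, config.tau)
            p_placebo = float(expit(mu))
            p_drug = float(expit(mu + delta))
            studies.append(TwoArmStudy(
                study_id=f"{drug}-{j + 1:02d}",
                drug=drug,
                outcome=outcome,
                drug_arm=ArmCount(int(rng.binomial(n, p_drug)), n),
                placebo_arm=ArmCount(int(rng.binomial(n, p_placebo)), n),
                covariates=covariates,
            ))
    return EvidenceNetwork(outcome, studies)


def true_league_table(
    config: SyntheticConfig, outcome: FractureOutcome | str = FractureOutcome.VERTEBRAL
) -> LeagueTable:
    """Oracle pairwise table of true ORs ``exp(d_A - d_C)`` for a scenario."""
    outcome = FractureOutcome(outcome)
    drugs = config.drugs
    cells: dict[tuple[str, str], LeagueCell] = {}
    for a in drugs:
        for c in drugs:
            if a == c:
                continue
            diff = config.true_log_or[a] - config.true_log_or[c]
            est = EffectEstimate(
                log_or=diff, se=1e-12 if diff == 0 else abs(diff) * 1e-12 + 1e-12,
                method="bucher", drug=a,
                ci_low=math.exp(diff) * (1 - 1e-9),
                ci_high=math.exp(diff) * (1 + 1e-9),
            )
            cells[(a, c)] = LeagueCell(estimate=est, significant=None)
    return LeagueTable(outcome=outcome, drugs=drugs, cells=cells)


def true_best_drug(config: SyntheticConfig) -> str:
    """Most protective drug under the scenario truth (smallest log-OR)."""
    return min(config.true_log_or, key=config.true_log_or.get)


def approx_pooled_se(config: SyntheticConfig, drug: str) -> float:
    """Large-sample pooled standard error of a drug's log-OR in the scenario.

    Uses expected cell counts at the mean baseline logit; serves to express
    planted effect separations in units of estimation uncertainty.
    """
    n = config._arm_size(drug)
    p0 = float(expit(config.baseline_logit_mean))
    p1 = float(expit(config.baseline_logit_mean + config.true_log_or[drug]))
    var_study = (
        1 / (n * p1) + 1 / (n * (1 - p1)) + 1 / (n * p0) + 1 / (n * (1 - p0))
    )
    k = config.studies_per_drug[drug]
    return math.sqrt(var_study / k)


def planted_winner_config(
    config: SyntheticConfig, drug: str, margin_se: float = 5.0
) -> SyntheticConfig:
    """Re-plant one drug's true effect ``margin_se`` pooled-SEs below all others.

    The planted log-OR is set so that, for every other drug j, the separation
    d_planted <= d_j - margin_se * sqrt(se_planted^2 + se_j^2) holds under
    the scenario's large-sample pooled standard errors.
    """
    if drug not in config.true_log_or:
        raise KeyError(drug)
    se_p = approx_pooled_se(config, drug)
    bound = min(
        config.true_log_or[j] - margin_se * math.sqrt(se_p**2 + approx_pooled_se(config, j)**2)
        for j in config.true_log_or if j != drug
    )
    new_truth = dict(config.true_log_or)
    new_truth[drug] = bound
    return replace(config, true_log_or=new_truth)


def load_scenario(
    source, outcome: FractureOutcome | str, seed: int = 0
) -> SyntheticConfig:
    """Build a SyntheticConfig for one outcome from a YAML scenario mapping.

    ``source`` is a path to a YAML file or an already-parsed mapping. The
    scenario lists, per outcome, a placebo event rate and per-drug true odds
    ratios; global keys give arm size, between-study spreads and study
    counts (drugs absent from an outcome are dropped from its study-count
    map).
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    outcome = FractureOutcome(outcome)
    try:
        block = raw["outcomes"][outcome.value]
    except KeyError as err:
        raise KeyError(f"scenario has no outcome block {outcome.value!r}") from err
    true_or = {d: float(v) for d, v in block["true_or"].items()}
    spd = {
        d: int(k) for d, k in raw.get("studies_per_drug", {}).items() if d in true_or
    }
    cov = raw.get("covariate_model")
    return SyntheticConfig(
        true_log_or={d: math.log(v) for d, v in true_or.items()},
        baseline_logit_mean=float(logit(float(block["placebo_rate"]))),
        baseline_logit_sd=float(raw.get("baseline_logit_sd", 0.0)),
        tau=float(raw.get("tau", 0.0)),
        studies_per_drug=spd,
        arm_size=raw.get("arm_size", 1000),
        covariate_model=CovariateModel(**cov) if cov else None,
        seed=seed,
    )


def paperlike_config(
    outcome: FractureOutcome | str = FractureOutcome.VERTEBRAL, seed: int = 0
) -> SyntheticConfig:
    """The packaged default scenario emulating the published nine-drug network."""
    ref = resources.files("starnma").joinpath("data_files/paperlike.yaml")
    with resources.as_file(ref) as p:
        return load_scenario(p, outcome, seed=seed)
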