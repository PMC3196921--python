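"""Data model and I/O for two-arm placebo-controlled fracture trials.

The unit of analysis is a randomized placebo-controlled trial (RPCT) that
reports fracture counts for one active osteoporosis drug versus placebo, for
one fracture site. A collection of such trials sharing a fracture outcome
forms a star-shaped evidence network with placebo as the common comparator:
every drug is connected to placebo and drugs are never compared head-to-head,
which is exactly the geometry that indirect treatment comparison methods
(Bucher division of odds ratios, Bayesian network meta-analysis) address.

Effect measures live on the log odds-ratio scale throughout; protective drug
effects are negative log odds ratios (OR < 1 for drug vs placebo).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: normal multiplier for 95% intervals and the matching back-calculation divisor
Z_95 = 1.96
CI_DIVISOR = 2 * Z_95  # 3.92

NETWORK_CSV_COLUMNS = [
    "study_id", "drug", "outcome",
    "events_drug", "n_drug", "events_placebo", "n_placebo",
    "followup_years", "mean_age", "years_since_menopause",
    "bmd_hip", "prior_vert_fracture_pct",
]

SUMMARY_CSV_COLUMNS = ["drug", "outcome", "or", "ci_low", "ci_high"]


class FractureOutcome(str, Enum):
    """The four fracture sites analysed: non-vertebral, vertebral, hip, wrist."""

    NONVERTEBRAL = "nonvertebral"
    VERTEBRAL = "vertebral"
    HIP = "hip"
    WRIST = "wrist"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class NonInformativeStudyError(ValueError):
    """Raised when a study carries no odds-ratio information.

    A trial with zero events in both arms, or with every patient fracturing
    in both arms, has an undefined odds ratio even after continuity
    correction; such studies are excluded from pooling.
    """


@dataclass(frozen=True)
class ArmCount:
    """Event count for one trial arm: ``events`` fractured out of ``total``."""

    events: int
    total: int

    def __post_init__(self) -> None:
        if not (isinstance(self.events, int) and isinstance(self.total, int)):
            raise TypeError("arm counts must be integers")
        if self.total < 1:
            raise ValueError(f"arm total must be >= 1, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"events must satisfy 0 <= events <= total, got "
                f"{self.events}/{self.total}"
            )

    @property
    def rate(self) -> float:
        return self.events / self.total


# plausibility bounds for baseline covariates (units in field names)
_COVARIATE_BOUNDS = {
    "mean_age": (30.0, 100.0),
    "years_since_menopause": (0.0, 60.0),
    "bmd_hip": (0.1, 1.5),
    "prior_vert_fracture_pct": (0.0, 100.0),
}


@dataclass(frozen=True)
class StudyCovariates:
    """Study-level baseline characteristics.

    Missing values are ``None`` and stay ``None`` — they are never imputed as
    zero. Present values are validated against plausibility bounds.
    """

    mean_age: float | None = None            # years
    years_since_menopause: float | None = None  # years
    bmd_hip: float | None = None             # g/cm^2 at the hip
    prior_vert_fracture_pct: float | None = None  # % with prior vertebral fx
    followup: float | None = None            # years of follow-up

    def __post_init__(self) -> None:
        for name, (lo, hi) in _COVARIATE_BOUNDS.items():
            value = getattr(self, name)
            if value is not None and not lo <= value <= hi:
                raise ValueError(
                    f"{name}={value} outside plausibility bounds [{lo}, {hi}]"
                )
        if self.followup is not None and self.followup <= 0:
            raise ValueError(f"followup must be > 0 years, got {self.followup}")

    def get(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass(frozen=True)
class TwoArmStudy:
    """One RPCT's arm counts for one fracture outcome, plus covariates."""

    study_id: str
    drug: str
    outcome: FractureOutcome
    drug_arm: ArmCount
    placebo_arm: ArmCount
    covariates: StudyCovariates = field(default_factory=StudyCovariates)

    def __post_init__(self) -> None:
        if self.drug.strip().lower() == "placebo":
            raise ValueError("the active arm must not be labelled 'placebo'")
        object.__setattr__(self, "outcome", FractureOutcome(self.outcome))


@dataclass(frozen=True)
class EvidenceNetwork:
    """Star-shaped collection of placebo-controlled trials for one outcome.

    Placebo is the implicit reference treatment: every study compares one
    drug against it, so the network geometry is a star and contains no
    closed loops. An explicitly empty network (no studies) is permitted only
    when the drug set is supplied, which supports prior-only posterior runs.
    """

    outcome: FractureOutcome
    studies: tuple[TwoArmStudy, ...]
    _drugs: tuple[str, ...] | None = None

    def __init__(
        self,
        outcome: FractureOutcome | str,
        studies: Iterable[TwoArmStudy],
        drugs: Sequence[str] | None = None,
    ) -> None:
        outcome = FractureOutcome(outcome)
        studies = tuple(studies)
        if not studies and drugs is None:
            raise ValueError(
                "a network needs at least one study (or an explicit drug list "
                "for prior-only use)"
            )
        seen: set[str] = set()
        for s in studies:
            if s.outcome != outcome:
                raise ValueError(
                    f"study {s.study_id!r} has outcome {s.outcome}, network "
                    f"is for {outcome}"
                )
            if s.study_id in seen:
                raise ValueError(
                    f"duplicate (study_id, outcome): ({s.study_id!r}, {outcome})"
                )
            seen.add(s.study_id)
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "studies", studies)
        object.__setattr__(
            self, "_drugs", tuple(sorted(drugs)) if drugs is not None else None
        )

    @property
    def drugs(self) -> tuple[str, ...]:
        """Sorted drug labels present in the network."""
        if self._drugs is not None:
            return self._drugs
        return tuple(sorted({s.drug for s in self.studies}))

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def studies_for(self, drug: str) -> tuple[TwoArmStudy, ...]:
        return tuple(s for s in self.studies if s.drug == drug)

    def subset(self, excluded_study_ids: Iterable[str]) -> "EvidenceNetwork":
        excluded = set(excluded_study_ids)
        unknown = excluded - {s.study_id for s in self.studies}
        if unknown:
            raise KeyError(f"unknown study ids: {sorted(unknown)}")
        kept = [s for s in self.studies if s.study_id not in excluded]
        if not kept:
            raise ValueError("excluding all studies leaves an empty network")
        return EvidenceNetwork(self.outcome, kept)


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error and 95% interval.

    For classical methods the interval is the symmetric normal interval
    ``exp(log_or ± 1.96·se)``; posterior estimates carry quantile-based
    intervals and imported published summaries carry the interval as printed,
    so ``ci_low``/``ci_high`` may be supplied explicitly.
    """

    log_or: float
    se: float
    method: str  # single_study | fixed | random | bucher | posterior
    ci_low: float | None = None
    ci_high: float | None = None
    drug: str | None = None
    outcome: FractureOutcome | None = None
    study_id: str | None = None
    p_value: float | None = None

    _METHODS = ("single_study", "fixed", "random", "bucher", "posterior")

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValueError("log_or must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"se must be a positive real, got {self.se}")
        if self.method not in self._METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if self.outcome is not None:
            object.__setattr__(self, "outcome", FractureOutcome(self.outcome))
        if self.ci_low is None:
            object.__setattr__(self, "ci_low", math.exp(self.log_or - Z_95 * self.se))
        if self.ci_high is None:
            object.__setattr__(self, "ci_high", math.exp(self.log_or + Z_95 * self.se))
        if not self.ci_low < self.or_value < self.ci_high:
            raise ValueError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket "
                f"OR {self.or_value}"
            )

    @property
    def or_value(self) -> float:
        return math.exp(self.log_or)

    @property
    def z_value(self) -> float:
        return self.log_or / self.se

    @property
    def significant(self) -> bool:
        """True when the 95% interval excludes OR = 1."""
        return self.ci_high < 1.0 or self.ci_low > 1.0

    def retagged(self, method: str, **kwargs) -> "EffectEstimate":
        return replace(self, method=method, **kwargs)


@dataclass(frozen=True)
class LeagueCell:
    """One drug-vs-drug contrast in a league table; ``estimate`` None = NR."""

    estimate: EffectEstimate | None
    nnt: float | None = None
    significant: bool | None = None

    @property
    def is_nr(self) -> bool:
        return self.estimate is None


@dataclass
class LeagueTable:
    """All ordered pairwise drug contrasts for one fracture outcome.

    ``cells[(a, c)]`` holds the contrast of drug ``a`` versus drug ``c`` on
    the odds-ratio scale; reciprocal cells satisfy OR(a,c)·OR(c,a) = 1 for
    classical constructions. Cells are NR when a drug lacks data for the
    outcome.
    """

    outcome: FractureOutcome
    drugs: tuple[str, ...]
    cells: dict[tuple[str, str], LeagueCell]

    def cell(self, a: str, c: str) -> LeagueCell:
        return self.cells[(a, c)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, c), cell in sorted(self.cells.items()):
            if cell.is_nr:
                rows.append({"comparison": f"{a} vs {c}", "or": None,
                             "ci_low": None, "ci_high": None, "p_value": None,
                             "nnt": cell.nnt, "significant": None, "nr": True})
            else:
                e = cell.estimate
                rows.append({"comparison": f"{a} vs {c}", "or": e.or_value,
                             "ci_low": e.ci_low, "ci_high": e.ci_high,
                             "p_value": e.p_value, "nnt": cell.nnt,
                             "significant": cell.significant, "nr": False})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NR")

    def to_dict(self) -> dict:
        out: dict = {"outcome": self.outcome.value, "cells": {}}
        for (a, c), cell in sorted(self.cells.items()):
            key = f"{a} vs {c}"
            if cell.is_nr:
                out["cells"][key] = "NR"
            else:
                e = cell.estimate
                out["cells"][key] = {
                    "or": e.or_value, "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "p_value": e.p_value, "nnt": cell.nnt,
                    "significant": cell.significant,
                }
        return out


def log_odds_ratio(study: TwoArmStudy, correction: float = 0.5) -> EffectEstimate:
    """Log odds ratio of the drug arm versus the placebo arm of one study.

    The 2x2 cells are (a, b) = drug (events, non-events) and (c, d) = placebo
    (events, non-events); ``log_or = ln[(a/b)/(c/d)]`` with the usual
    large-sample standard error ``sqrt(1/a + 1/b + 1/c + 1/d)``. When any
    cell is zero, ``correction`` (default 0.5) is added to all four cells.
    Protective drugs give negative values.

    Raises :class:`NonInformativeStudyError` for double-zero or double-full
    studies, whose odds ratio is undefined.
    """
    if correction < 0:
        raise ValueError("correction must be >= 0")
    a = float(study.drug_arm.events)
    b = float(study.drug_arm.total - study.drug_arm.events)
    c = float(study.placebo_arm.events)
    d = float(study.placebo_arm.total - study.placebo_arm.events)
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise NonInformativeStudyError(
            f"study {study.study_id!r}: both arms have "
            f"{'no' if a == 0 else 'only'} events; odds ratio undefined"
        )
    if 0.0 in (a, b, c, d):
        if correction == 0:
            raise ZeroDivisionError(
                f"study {study.study_id!r} has a zero cell and correction=0"
            )
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    log_or = math.log(a / b) - math.log(c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        log_or=log_or, se=se, method="single_study",
        drug=study.drug, outcome=study.outcome, study_id=study.study_id,
    )


def network_effects(
    network: EvidenceNetwork, correction: float = 0.5
) -> list[EffectEstimate]:
    """Per-study log odds ratios, dropping non-informative studies with a log."""
    out = []
    for study in network.studies:
        try:
            out.append(log_odds_ratio(study, correction=correction))
        except NonInformativeStudyError as err:
            logger.warning("excluded non-informative study: %s", err)
    return out


def _parse_optional_float(raw: str) -> float | None:
    raw = raw.strip()
    if raw == "" or raw.upper() == "NR":
        return None
    return float(raw)


def read_network_csv(path, outcome: FractureOutcome | str) -> EvidenceNetwork:
    """Read arm-level trial summaries for one outcome from CSV.

    The file must carry exactly the documented header; rows for other
    outcomes are ignored and missing covariate cells (empty or "NR") are
    preserved as missing. Validation errors name the offending row.
    """
    outcome = FractureOutcome(outcome)
    studies: list[TwoArmStudy] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        unknown = [c for c in header if c not in NETWORK_CSV_COLUMNS]
        missing = [c for c in NETWORK_CSV_COLUMNS if c not in header]
        if unknown:
            raise ValueError(f"unknown column(s) in {path}: {unknown}")
        if missing:
            raise ValueError(f"missing column(s) in {path}: {missing}")
        for lineno, row in enumerate(reader, start=2):
            if row["outcome"].strip() != outcome.value:
                continue
            try:
                study = TwoArmStudy(
                    study_id=row["study_id"].strip(),
                    drug=row["drug"].strip(),
                    outcome=outcome,
                    drug_arm=ArmCount(int(row["events_drug"]), int(row["n_drug"])),
                    placebo_arm=ArmCount(
                        int(row["events_placebo"]), int(row["n_placebo"])
                    ),
                    covariates=StudyCovariates(
                        mean_age=_parse_optional_float(row["mean_age"]),
                        years_since_menopause=_parse_optional_float(
                            row["years_since_menopause"]
                        ),
                        bmd_hip=_parse_optional_float(row["bmd_hip"]),
                        prior_vert_fracture_pct=_parse_optional_float(
                            row["prior_vert_fracture_pct"]
                        ),
                        followup=_parse_optional_float(row["followup_years"]),
                    ),
                )
            except (ValueError, TypeError) as err:
                raise ValueError(f"{path} row {lineno}: {err}") from err
            studies.append(study)
    return EvidenceNetwork(outcome, studies)


def write_network_csv(networks: EvidenceNetwork | Iterable[EvidenceNetwork], path) -> None:
    """Write one or more networks to the arm-level CSV schema (lossless)."""
    if isinstance(networks, EvidenceNetwork):
        networks = [networks]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(NETWORK_CSV_COLUMNS)
        for network in networks:
            for s in network.studies:
                cov = s.covariates

                def fmt(v):
                    return "" if v is None else repr(v)

                writer.writerow([
                    s.study_id, s.drug, s.outcome.value,
                    s.drug_arm.events, s.drug_arm.total,
                    s.placebo_arm.events, s.placebo_arm.total,
                    fmt(cov.followup), fmt(cov.mean_age),
                    fmt(cov.years_since_menopause), fmt(cov.bmd_hip),
                    fmt(cov.prior_vert_fracture_pct),
                ])


def summary_to_estimate(
    or_value: float,
    ci_low: float,
    ci_high: float,
    drug: str | None = None,
    outcome: FractureOutcome | str | None = None,
) -> EffectEstimate:
    """Back-calculate a log-OR estimate from a published OR and 95% interval.

    The standard error is recovered from the interval width on the log scale,
    ``se = (ln ci_high - ln ci_low) / 3.92``; the printed interval is kept as
    given (published intervals need not be exactly symmetric on the log scale
    around the printed point estimate).
    """
    if or_value <= 0 or ci_low <= 0 or ci_high <= 0:
        raise ValueError("OR and interval limits must be positive")
    if ci_low >= ci_high:
        raise ValueError(
            f"degenerate interval: ci_low={ci_low} >= ci_high={ci_high}"
        )
    se = (math.log(ci_high) - math.log(ci_low)) / CI_DIVISOR
    return EffectEstimate(
        log_or=math.log(or_value), se=se, method="single_study",
        ci_low=ci_low, ci_high=ci_high, drug=drug,
        outcome=FractureOutcome(outcome) if outcome is not None else None,
    )


def read_summary_csv(path) -> list[EffectEstimate]:
    """Read published drug-vs-placebo OR summaries (drug, outcome, or, ci)."""
    out: list[EffectEstimate] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in SUMMARY_CSV_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"missing column(s) in {path}: {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(summary_to_estimate(
                    float(row["or"]), float(row["ci_low"]), float(row["ci_high"]),
                    drug=row["drug"].strip(), outcome=row["outcome"].strip(),
                ))
            except ValueError as err:
                raise ValueError(f"{path} row {lineno}: {err}") from err
    return out


def load_published_summaries() -> pd.DataFrame:
    """Published per-drug odds-ratio summaries from a nine-drug indirect
    treatment comparison of osteoporosis medications.

    Returns a tidy frame with one row per (analysis block, drug, outcome):
    ``analysis`` is "classical" or "bayesian"; classical rows carry the
    placebo event rate (%), Bayesian rows carry the reported probability of
    being most efficacious (NaN where printed only as an inequality) and the
    reported effect size. NR cells are absent rows.
    """
    ref = resources.files("starnma").joinpath("data_files/published_or_summaries.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    df["prob"] = pd.to_numeric(df["prob"], errors="coerce")
    return df


def published_estimates(
    analysis: str = "bayesian", outcome: FractureOutcome | str | None = None
) -> dict[tuple[str, str], EffectEstimate]:
    """Published summaries as EffectEstimates keyed by (drug, outcome)."""
    df = load_published_summaries()
    df = df[df["analysis"] == analysis]
    if outcome is not None:
        df = df[df["outcome"] == FractureOutcome(outcome).value]
    out = {}
    for _, row in df.iterrows():
        out[(row["drug"], row["outcome"])] = summary_to_estimate(
            row["or"], row["ci_low"], row["ci_high"],
            drug=row["drug"], outcome=row["outcome"],
        )
    return out
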