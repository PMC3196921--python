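"""Bucher adjusted indirect comparison through a common placebo comparator.

For drugs A and C each compared with placebo B, the indirect log odds ratio
is logOR(A vs C) = logOR(A vs B) - logOR(C vs B) with variances adding,
se² = se_AB² + se_CB². The method is exact on a star network (no closed
loops exist, so no internal consistency check is possible) and the indirect
standard error always exceeds either input standard error.
"""

from __future__ import annotations

import math
from typing import Mapping

from scipy import stats

from .data import (
    EffectEstimate,
    FractureOutcome,
    LeagueCell,
    LeagueTable,
)


def indirect_comparison(ab: EffectEstimate, cb: EffectEstimate) -> EffectEstimate:
    """Indirect drug-A-vs-drug-C estimate from two drug-vs-placebo estimates.

    Both inputs must share the placebo comparator and the outcome; the
    result carries a two-sided z-test p-value and the ``bucher`` method tag.
    """
    if ab.outcome is not None and cb.outcome is not None and ab.outcome != cb.outcome:
        raise ValueError(
            f"outcome mismatch: {ab.outcome} vs {cb.outcome}"
        )
    log_or = ab.log_or - cb.log_or
    se = math.sqrt(ab.se**2 + cb.se**2)
    p = 2.0 * float(stats.norm.sf(abs(log_or / se)))
    return EffectEstimate(
        log_or=log_or, se=se, method="bucher",
        drug=ab.drug, outcome=ab.outcome or cb.outcome, p_value=p,
    )


def bucher_league_table(
    per_drug: Mapping[str, EffectEstimate],
    outcome: FractureOutcome | str | None = None,
    nnt_baseline_risk: float | None = None,
) -> LeagueTable:
    """All ordered pairwise indirect comparisons among the pooled drugs.

    ``per_drug`` maps drug name to its pooled drug-vs-placebo estimate; a
    value of ``None`` marks a drug with no data for the outcome and yields
    NR cells. Reciprocal cells are exact inverses, and transitivity
    log(A,C) = log(A,B) + log(B,C) holds by construction. When
    ``nnt_baseline_risk`` is given, each cell also carries the number needed
    to treat at that comparator risk.
    """
    from .report import nnt as _nnt  # local import avoids a cycle

    drugs = tuple(sorted(per_drug))
    if len(drugs) < 2:
        raise ValueError("a league table needs >= 2 drugs")
    if outcome is None:
        outcome = next(
            (e.outcome for e in per_drug.values() if e is not None and e.outcome),
            None,
        )
    if outcome is None:
        raise ValueError("outcome could not be inferred; pass it explicitly")
    outcome = FractureOutcome(outcome)
    cells: dict[tuple[str, str], LeagueCell] = {}
    for a in drugs:
        for c in drugs:
            if a == c:
                continue
            ea, ec = per_drug[a], per_drug[c]
            if ea is None or ec is None:
                cells[(a, c)] = LeagueCell(estimate=None)
                continue
            est = indirect_comparison(ea, ec)
            value_nnt = None
            if nnt_baseline_risk is not None and not math.isclose(est.or_value, 1.0):
                value_nnt = _nnt(est.or_value, nnt_baseline_risk)
            cells[(a, c)] = LeagueCell(
                estimate=est, nnt=value_nnt, significant=est.significant
            )
    return LeagueTable(outcome=outcome, drugs=drugs, cells=cells)
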