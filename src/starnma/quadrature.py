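"""Exact posterior moments for tiny instances by numerical quadrature.

For a one-drug, one-study network the model has exactly two parameters
(the baseline logit mu and the drug effect d), so the posterior can be
integrated on a dense 2-D grid to essentially machine precision. This
provides a sampler-independent gold standard: the densities are evaluated
with scipy's binomial pmf and normal pdf directly, not through the MCMC
code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp

from .bayes import MCMCConfig
from .data import EvidenceNetwork, TwoArmStudy


@dataclass(frozen=True)
class PosteriorMoments:
    mean_d: float
    sd_d: float
    mean_mu: float
    sd_mu: float


def _crude_logit(events: int, total: int) -> float:
    return math.log((events + 0.5) / (total - events + 0.5))


def posterior_moments_1study(
    study: TwoArmStudy,
    config: MCMCConfig = MCMCConfig(),
    grid_points: int = 801,
    half_width_se: float = 10.0,
) -> PosteriorMoments:
    """Posterior mean and SD of (d, mu) for a single two-arm study.

    The grid is centred on the crude empirical logits and spans
    ``half_width_se`` large-sample standard errors each side, which covers
    the posterior mass to far beyond double precision for non-degenerate
    counts.
    """
    rp, n0 = study.placebo_arm.events, study.placebo_arm.total
    rd, n1 = study.drug_arm.events, study.drug_arm.total
    mu_hat = _crude_logit(rp, n0)
    d_hat = _crude_logit(rd, n1) - mu_hat
    se_mu = math.sqrt(1 / (rp + 0.5) + 1 / (n0 - rp + 0.5))
    se_d = math.sqrt(se_mu**2 + 1 / (rd + 0.5) + 1 / (n1 - rd + 0.5))
    mu_grid = np.linspace(mu_hat - half_width_se * se_mu,
                          mu_hat + half_width_se * se_mu, grid_points)
    d_grid = np.linspace(d_hat - half_width_se * se_d,
                         d_hat + half_width_se * se_d, grid_points)
    mu2, d2 = np.meshgrid(mu_grid, d_grid, indexing="ij")
    log_post = (
        stats.binom.logpmf(rp, n0, expit(mu2))
        + stats.binom.logpmf(rd, n1, expit(mu2 + d2))
        + stats.norm.logpdf(mu2, 0.0,
                            1.0 / math.sqrt(config.prior_precision_baseline))
        + stats.norm.logpdf(d2, config.prior_mean_d,
                            1.0 / math.sqrt(config.prior_precision_d))
    )
    log_post -= logsumexp(log_post)
    w = np.exp(log_post)
    mean_d = float(np.sum(w * d2))
    sd_d = float(math.sqrt(np.sum(w * (d2 - mean_d) ** 2)))
    mean_mu = float(np.sum(w * mu2))
    sd_mu = float(math.sqrt(np.sum(w * (mu2 - mean_mu) ** 2)))
    return PosteriorMoments(mean_d=mean_d, sd_d=sd_d,
                            mean_mu=mean_mu, sd_mu=sd_mu)


def mcmc_vs_quadrature(
    study: TwoArmStudy, config: MCMCConfig
) -> dict[str, float]:
    """Relative errors (in %) of MCMC posterior mean/SD of d against quadrature."""
    from .bayes import run_mcmc

    net = EvidenceNetwork(study.outcome, [study])
    exact = posterior_moments_1study(study, config)
    draws = run_mcmc(net, config)
    mean_mcmc = float(draws.d[:, 0].mean())
    sd_mcmc = float(draws.d[:, 0].std(ddof=1))
    return {
        "mean_rel_err_pct": 100.0 * abs(mean_mcmc - exact.mean_d) / abs(exact.mean_d),
        "sd_rel_err_pct": 100.0 * abs(sd_mcmc - exact.sd_d) / exact.sd_d,
        "mean_mcmc": mean_mcmc, "sd_mcmc": sd_mcmc,
        "mean_exact": exact.mean_d, "sd_exact": exact.sd_d,
    }
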