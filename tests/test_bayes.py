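"""Bayesian network model: log density, sampler, summaries, rankings."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from starnma import (
    ArmCount,
    EvidenceNetwork,
    MCMCConfig,
    PosteriorDraws,
    PosteriorSummary,
    TwoArmStudy,
    effect_size,
    effect_size_from_interval,
    log_odds_ratio,
    log_posterior,
    pairwise_contrasts,
    prob_best,
    run_mcmc,
    summarize_posteriors,
)

FAST = MCMCConfig(chains=2, iterations=4000, burn_in=2000, seed=99)


def study(events_drug, n_drug, events_placebo, n_placebo, drug="a", sid="s1"):
    return TwoArmStudy(
        study_id=sid, drug=drug, outcome="vertebral",
        drug_arm=ArmCount(events_drug, n_drug),
        placebo_arm=ArmCount(events_placebo, n_placebo),
    )


class TestLogPosterior:
    def test_empty_network_equals_prior_density(self):
        net = EvidenceNetwork("vertebral", [], drugs=["a", "b"])
        cfg = MCMCConfig()
        d = [0.5, -1.0]
        value = log_posterior(net, d, [], cfg)
        expected = sum(-0.5 * cfg.prior_precision_d * v**2 for v in d)
        assert value == pytest.approx(expected, rel=1e-12)
        # prior-dominated density decreases as the parameters move out
        assert log_posterior(net, [5.0, -10.0], [], cfg) < value

    def test_mle_dominates_shifted_parameters(self):
        net = EvidenceNetwork("vertebral", [study(10, 100, 30, 100)])
        mle_mu = math.log(30 / 70)
        mle_d = math.log((10 / 90) / (30 / 70))
        at_mle = log_posterior(net, [mle_d], [mle_mu])
        assert at_mle > log_posterior(net, [mle_d + 10], [mle_mu])

    def test_density_ratios_match_independent_evaluation(self):
        net = EvidenceNetwork("vertebral", [study(3, 20, 7, 25)])
        cfg = MCMCConfig()

        def brute(d, mu):
            p0, p1 = expit(mu), expit(mu + d)
            return (
                stats.binom.logpmf(7, 25, p0)
                + stats.binom.logpmf(3, 20, p1)
                + stats.norm.logpdf(mu, 0, math.sqrt(1000.0))
                + stats.norm.logpdf(d, 0, math.sqrt(1000.0))
            )

        points = [(-0.5, -1.0), (0.3, -0.2), (1.2, 0.4)]
        ours = [log_posterior(net, [d], [mu], cfg) for d, mu in points]
        ref = [brute(d, mu) for d, mu in points]
        for i in range(1, len(points)):
            assert ours[i] - ours[0] == pytest.approx(ref[i] - ref[0], abs=1e-9)

    def test_nonfinite_parameters_rejected(self):
        net = EvidenceNetwork("vertebral", [study(3, 20, 7, 25)])
        with pytest.raises(ValueError):
            log_posterior(net, [float("nan")], [0.0])
        with pytest.raises(ValueError):
            log_posterior(net, [0.0, 0.0], [0.0])  # wrong dimension


class TestSampler:
    def test_same_seed_reproduces_draws_exactly(self):
        net = EvidenceNetwork("vertebral", [study(10, 100, 20, 100)])
        a = run_mcmc(net, FAST)
        b = run_mcmc(net, FAST)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.mu, b.mu)

    def test_prior_only_run_recovers_prior_sd(self):
        net = EvidenceNetwork("vertebral", [], drugs=["a"])
        cfg = MCMCConfig(chains=2, iterations=30_000, burn_in=10_000, seed=12)
        draws = run_mcmc(net, cfg)
        sd = float(draws.d.std(ddof=1))
        assert sd == pytest.approx(math.sqrt(1000.0), rel=0.05)

    def test_posterior_concentrates_on_large_study_mle(self):
        big = study(900, 100_000, 1800, 100_000)
        net = EvidenceNetwork("vertebral", [big])
        draws = run_mcmc(net, MCMCConfig(chains=2, iterations=6000,
                                         burn_in=3000, seed=4))
        sample_lor = log_odds_ratio(big).log_or
        post_mean = float(draws.d.mean())
        post_sd = float(draws.d.std(ddof=1))
        assert abs(post_mean - sample_lor) < 3 * post_sd
        assert post_sd < 0.05


class TestSummaries:
    def make_draws(self, d, drugs=("x", "y")):
        d = np.asarray(d, dtype=float)
        return PosteriorDraws(
            d=d, mu=np.zeros((d.shape[0], 0)),
            chain_labels=np.zeros(d.shape[0], dtype=int),
            drugs=tuple(drugs[: d.shape[1]]), study_ids=(),
            outcome="vertebral",
        )

    def test_constant_draws_give_point_summary(self):
        draws = self.make_draws(np.full((2000, 1), math.log(0.5)), drugs=("x",))
        s = summarize_posteriors(draws)[0]
        assert s.or_mean == pytest.approx(0.5)
        assert (s.cri_low, s.cri_high) == (pytest.approx(0.5), pytest.approx(0.5))
        assert s.or_sd == pytest.approx(0.0)

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(6)
        log_draws = rng.normal(0.0, 0.01, size=(200_000, 1))
        s = summarize_posteriors(self.make_draws(log_draws, drugs=("x",)))[0]
        # geometric-mean convention: point estimate is exp of the mean log OR
        assert s.or_mean == pytest.approx(math.exp(log_draws.mean()), rel=1e-9)
        assert s.or_mean == pytest.approx(1.0, abs=2e-4)
        assert s.cri_low == pytest.approx(math.exp(-0.0196), abs=3e-4)
        assert s.cri_high == pytest.approx(math.exp(0.0196), abs=3e-4)
        # the OR-draw SD keeps the arithmetic-scale spread
        assert s.or_sd == pytest.approx(0.01, rel=0.05)

    def test_too_few_draws_rejected(self):
        draws = self.make_draws(np.zeros((500, 1)), drugs=("x",))
        with pytest.raises(ValueError, match="1000"):
            summarize_posteriors(draws)

    def test_prob_best_brute_force_example(self):
        draws = self.make_draws(
            [[-1, 0], [0.5, -0.2], [-0.3, -0.4], [-2, 1]]
        )
        assert prob_best(draws) == {"x": 0.5, "y": 0.5}

    def test_prob_best_single_drug(self):
        draws = self.make_draws(np.zeros((100, 1)), drugs=("x",))
        assert prob_best(draws) == {"x": 1.0}

    def test_prob_best_splits_exact_ties(self):
        col = np.linspace(-1, 1, 100)[:, None]
        draws = self.make_draws(np.hstack([col, col]))
        assert prob_best(draws) == {"x": 0.5, "y": 0.5}

    def test_prob_best_sums_to_one(self):
        rng = np.random.default_rng(8)
        draws = self.make_draws(rng.normal(size=(5000, 4)),
                                drugs=("a", "b", "c", "d"))
        assert sum(prob_best(draws).values()) == pytest.approx(1.0, abs=1e-12)


class TestEffectSize:
    @pytest.mark.parametrize("or_v,lo,hi,expected,tol", [
        (0.81, 0.66, 0.96, 16.1, 0.1),   # published non-vertebral values
        (0.77, 0.60, 0.91, 16.4, 0.1),
        (0.28, 0.19, 0.40, 66.2, 1.0),   # published vertebral zoledronic value
    ])
    def test_reconstructs_published_values(self, or_v, lo, hi, expected, tol):
        assert effect_size_from_interval(or_v, lo, hi) == pytest.approx(
            expected, abs=tol
        )

    def test_unit_or_with_sd(self):
        assert effect_size(1.0, 0.5) == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            effect_size(0.8, 0.0)


class TestPairwiseContrasts:
    def test_constant_draw_contrast(self):
        d = np.tile([math.log(0.28), math.log(0.60)], (2000, 1))
        draws = TestSummaries().make_draws(d, drugs=("zol", "ris"))
        table = pairwise_contrasts(draws)
        assert table.cell("zol", "ris").estimate.or_value == pytest.approx(
            0.28 / 0.60, rel=1e-9
        )

    def test_reciprocal_cells_multiply_to_one(self):
        rng = np.random.default_rng(3)
        draws = TestSummaries().make_draws(rng.normal(size=(4000, 2)))
        table = pairwise_contrasts(draws)
        ab = table.cell("x", "y").estimate.or_value
        ba = table.cell("y", "x").estimate.or_value
        # geometric-mean contrasts are exactly reciprocal
        assert ab * ba == pytest.approx(1.0, rel=1e-9)
        diff = draws.d[:, 0] - draws.d[:, 1]
        assert ab == pytest.approx(math.exp(float(diff.mean())), rel=1e-9)
        assert table.cell("x", "y").estimate.se == pytest.approx(
            table.cell("y", "x").estimate.se
        )

    def test_single_drug_rejected(self):
        draws = TestSummaries().make_draws(np.zeros((100, 1)), drugs=("x",))
        with pytest.raises(ValueError):
            pairwise_contrasts(draws)
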