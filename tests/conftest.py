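import pytest

from starnma import (
    ArmCount,
    EvidenceNetwork,
    MCMCConfig,
    StudyCovariates,
    TwoArmStudy,
    generate_network,
    paperlike_config,
    pool_by_drug,
    run_mcmc,
    summarize_posteriors,
)


@pytest.fixture
def simple_study():
    return TwoArmStudy(
        study_id="trial-1",
        drug="alendronate",
        outcome="vertebral",
        drug_arm=ArmCount(10, 100),
        placebo_arm=ArmCount(20, 100),
        covariates=StudyCovariates(mean_age=67.0, bmd_hip=0.7, followup=3.0),
    )


@pytest.fixture
def tiny_network(simple_study):
    other = TwoArmStudy(
        study_id="trial-2",
        drug="risedronate",
        outcome="vertebral",
        drug_arm=ArmCount(12, 150),
        placebo_arm=ArmCount(25, 150),
    )
    return EvidenceNetwork("vertebral", [simple_study, other])


@pytest.fixture(scope="session")
def paperlike_run():
    """One reduced-length posterior run on the paperlike vertebral network,
    shared by the end-to-end checks (recovery, concordance, league tables)."""
    config = paperlike_config("vertebral", seed=20260)
    network = generate_network(config, "vertebral")
    mcmc = MCMCConfig(chains=2, iterations=10_000, burn_in=5_000, seed=20261)
    draws = run_mcmc(network, mcmc)
    return {
        "config": config,
        "network": network,
        "draws": draws,
        "summaries": summarize_posteriors(draws),
        "per_drug_fixed": pool_by_drug(network, method="fixed"),
    }
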