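"""Trial data model, odds-ratio arithmetic and CSV round trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from starnma import (
    ArmCount,
    EffectEstimate,
    EvidenceNetwork,
    FractureOutcome,
    NonInformativeStudyError,
    StudyCovariates,
    TwoArmStudy,
    load_published_summaries,
    log_odds_ratio,
    read_network_csv,
    read_summary_csv,
    summary_to_estimate,
    write_network_csv,
)


def make_study(events_drug, n_drug, events_placebo, n_placebo, **kwargs):
    defaults = dict(study_id="s", drug="alendronate", outcome="vertebral")
    defaults.update(kwargs)
    return TwoArmStudy(
        drug_arm=ArmCount(events_drug, n_drug),
        placebo_arm=ArmCount(events_placebo, n_placebo),
        **defaults,
    )


class TestValidation:
    def test_arm_count_bounds(self):
        with pytest.raises(ValueError):
            ArmCount(12, 10)
        with pytest.raises(ValueError):
            ArmCount(-1, 10)
        with pytest.raises(ValueError):
            ArmCount(0, 0)

    def test_four_outcomes_only(self):
        assert {o.value for o in FractureOutcome} == {
            "nonvertebral", "vertebral", "hip", "wrist"
        }
        with pytest.raises(ValueError):
            make_study(1, 10, 1, 10, outcome="femur")

    def test_drug_cannot_be_placebo(self):
        with pytest.raises(ValueError):
            make_study(1, 10, 1, 10, drug="placebo")

    def test_covariate_plausibility_bounds(self):
        with pytest.raises(ValueError):
            StudyCovariates(mean_age=200.0)
        with pytest.raises(ValueError):
            StudyCovariates(bmd_hip=2.5)
        assert StudyCovariates(mean_age=67.0).bmd_hip is None

    def test_network_rejects_duplicates_and_mixed_outcomes(self):
        a = make_study(1, 10, 2, 10, study_id="x")
        with pytest.raises(ValueError, match="duplicate"):
            EvidenceNetwork("vertebral", [a, a])
        b = make_study(1, 10, 2, 10, study_id="y", outcome="hip")
        with pytest.raises(ValueError, match="outcome"):
            EvidenceNetwork("vertebral", [a, b])

    def test_empty_network_needs_explicit_drugs(self):
        with pytest.raises(ValueError):
            EvidenceNetwork("vertebral", [])
        net = EvidenceNetwork("vertebral", [], drugs=["alendronate"])
        assert net.drugs == ("alendronate",)


class TestLogOddsRatio:
    def test_identical_arms_give_unit_or(self):
        est = log_odds_ratio(make_study(10, 100, 10, 100))
        assert est.log_or == pytest.approx(0.0, abs=1e-12)
        assert est.or_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # (10/90)/(20/80) = 0.4444; se = sqrt(1/10 + 1/90 + 1/20 + 1/80)
        est = log_odds_ratio(make_study(10, 100, 20, 100))
        assert est.or_value == pytest.approx(4.0 / 9.0, rel=1e-12)
        assert est.se == pytest.approx(
            math.sqrt(1 / 10 + 1 / 90 + 1 / 20 + 1 / 80), rel=1e-12
        )
        assert est.log_or < 0  # protective

    def test_continuity_correction_on_zero_cell(self):
        est = log_odds_ratio(make_study(0, 50, 5, 50), correction=0.5)
        expected = math.log((0.5 / 50.5) / (5.5 / 45.5))
        assert est.log_or == pytest.approx(expected, rel=1e-12)
        se = math.sqrt(1 / 0.5 + 1 / 50.5 + 1 / 5.5 + 1 / 45.5)
        assert est.se == pytest.approx(se, rel=1e-12)

    def test_no_correction_without_zero_cell(self):
        plain = log_odds_ratio(make_study(10, 100, 20, 100), correction=0.5)
        uncorrected = log_odds_ratio(make_study(10, 100, 20, 100), correction=0.0)
        assert plain.log_or == uncorrected.log_or

    def test_double_zero_and_double_full_are_non_informative(self):
        with pytest.raises(NonInformativeStudyError):
            log_odds_ratio(make_study(0, 50, 0, 50))
        with pytest.raises(NonInformativeStudyError):
            log_odds_ratio(make_study(50, 50, 30, 30))

    @given(
        a=st.integers(0, 50), c=st.integers(0, 50),
        n1=st.integers(50, 200), n2=st.integers(50, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_arm_swap(self, a, c, n1, n2):
        if (a == 0 and c == 0) or (a == n1 and c == n2):
            return
        fwd = log_odds_ratio(make_study(a, n1, c, n2))
        rev = log_odds_ratio(make_study(c, n2, a, n1))
        assert fwd.log_or == pytest.approx(-rev.log_or, abs=1e-12)
        assert fwd.se == pytest.approx(rev.se, abs=1e-12)


class TestEffectEstimate:
    def test_symmetric_interval_default(self):
        est = EffectEstimate(log_or=-0.5, se=0.2, method="fixed")
        assert est.ci_low == pytest.approx(math.exp(-0.5 - 1.96 * 0.2))
        assert est.ci_high == pytest.approx(math.exp(-0.5 + 1.96 * 0.2))
        assert est.significant

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            EffectEstimate(log_or=0.0, se=0.0, method="fixed")
        with pytest.raises(ValueError):
            EffectEstimate(log_or=0.0, se=0.5, method="bootstrap")


class TestSummaryImport:
    def test_published_alendronate_row(self):
        est = summary_to_estimate(0.81, 0.66, 0.96)
        assert est.log_or == pytest.approx(-0.2107, abs=2e-4)
        assert est.se == pytest.approx(0.09556, abs=5e-5)

    def test_hand_derived_se(self):
        est = summary_to_estimate(0.28, 0.19, 0.40)
        assert est.se == pytest.approx(
            (math.log(0.40) - math.log(0.19)) / 3.92, rel=1e-12
        )
        assert est.se == pytest.approx(0.1899, abs=1e-4)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            summary_to_estimate(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            summary_to_estimate(0.5, 0.8, 0.6)

    @given(
        log_or=st.floats(-1.5, 1.5),
        se=st.floats(0.05, 0.8),
    )
    @settings(max_examples=50, deadline=None)
    def test_se_backcalculation_inverts_symmetric_intervals(self, log_or, se):
        lo = math.exp(log_or - 1.96 * se)
        hi = math.exp(log_or + 1.96 * se)
        est = summary_to_estimate(math.exp(log_or), lo, hi)
        assert est.se == pytest.approx(se, rel=1e-9)
        # reconstructed interval reproduces the input to 3 decimals
        assert math.exp(est.log_or - 1.96 * est.se) == pytest.approx(lo, abs=5e-4)
        assert math.exp(est.log_or + 1.96 * est.se) == pytest.approx(hi, abs=5e-4)

    def test_summary_csv_roundtrip(self, tmp_path):
        path = tmp_path / "summaries.csv"
        path.write_text(
            "drug,outcome,or,ci_low,ci_high\n"
            "alendronate,vertebral,0.51,0.40,0.63\n"
            "zoledronic,vertebral,0.28,0.19,0.40\n"
        )
        rows = read_summary_csv(path)
        assert [r.drug for r in rows] == ["alendronate", "zoledronic"]
        assert rows[0].or_value == pytest.approx(0.51)

    def test_summary_csv_rejects_bad_interval(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("drug,outcome,or,ci_low,ci_high\nx,hip,1.0,1.0,1.0\n")
        with pytest.raises(ValueError, match="row 2"):
            read_summary_csv(path)


class TestNetworkCsv:
    def test_roundtrip_preserves_counts_and_covariates(self, tmp_path, tiny_network):
        path = tmp_path / "net.csv"
        write_network_csv(tiny_network, path)
        back = read_network_csv(path, "vertebral")
        assert back == tiny_network

    def test_outcome_filtering(self, tmp_path):
        path = tmp_path / "net.csv"
        header = ("study_id,drug,outcome,events_drug,n_drug,events_placebo,"
                  "n_placebo,followup_years,mean_age,years_since_menopause,"
                  "bmd_hip,prior_vert_fracture_pct\n")
        path.write_text(
            header
            + "a,alendronate,vertebral,5,100,9,100,3,NR,,0.7,10\n"
            + "b,alendronate,hip,2,100,4,100,3,67,,NR,\n"
        )
        vert = read_network_csv(path, "vertebral")
        assert vert.n_studies == 1
        assert vert.studies[0].covariates.mean_age is None  # "NR" stays missing
        hip = read_network_csv(path, "hip")
        assert hip.n_studies == 1

    def test_invalid_counts_name_the_row(self, tmp_path):
        path = tmp_path / "net.csv"
        header = ("study_id,drug,outcome,events_drug,n_drug,events_placebo,"
                  "n_placebo,followup_years,mean_age,years_since_menopause,"
                  "bmd_hip,prior_vert_fracture_pct\n")
        path.write_text(header + "a,alendronate,vertebral,12,10,9,100,3,,,,\n")
        with pytest.raises(ValueError, match="row 2"):
            read_network_csv(path, "vertebral")

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "net.csv"
        path.write_text("study_id,drug,outcome,bogus\n")
        with pytest.raises(ValueError, match="bogus"):
            read_network_csv(path, "vertebral")


def test_published_summaries_shape():
    df = load_published_summaries()
    assert set(df["analysis"]) == {"classical", "bayesian"}
    # NR cells are absent: no wrist rows for the three drugs lacking wrist data
    bay = df[df["analysis"] == "bayesian"]
    wrist = set(bay[bay["outcome"] == "wrist"]["drug"])
    assert {"denosumab", "ibandronate", "zoledronic"}.isdisjoint(wrist)
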