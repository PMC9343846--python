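"""Synthetic registry generator: determinism, calibration, round-trips."""

import math

import pandas as pd
import pytest
from pydantic import ValidationError

from fhrecall import synthetic
from fhrecall.adherence import classify_cohort
from fhrecall.config import GroupRates, SimulationConfig


class TestConfigValidation:
    def test_nonpositive_group_sizes_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_recalled=0)

    def test_e780_cannot_exceed_e78(self):
        with pytest.raises(ValidationError, match="p_e780"):
            SimulationConfig(
                p_e78=GroupRates(recalled=0.5, control=0.5),
                p_e780=GroupRates(recalled=0.6, control=0.4),
            )

    def test_empty_archetype_mix_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(archetype_mix=(0, 0, 0))

    def test_date_ordering_enforced(self):
        import datetime as dt

        with pytest.raises(ValidationError):
            SimulationConfig(visit_window=(dt.date(2001, 1, 1), dt.date(2002, 1, 1)))


class TestCohort:
    def test_group_sizes(self):
        cfg = SimulationConfig(n_recalled=34, n_controls=291, seed=1)
        participants, _ = synthetic.generate_cohort(cfg)
        assert len(participants) == 325
        assert (participants["group"] == "RECALLED").sum() == 34

    def test_minimal_cohort(self):
        cfg = SimulationConfig(n_recalled=1, n_controls=1, seed=7)
        participants, _ = synthetic.generate_cohort(cfg)
        assert sorted(participants["group"]) == ["CONTROL", "RECALLED"]

    def test_seeded_determinism_byte_identical(self, small_config):
        a = synthetic.generate_all(small_config)
        b = synthetic.generate_all(small_config)
        for name in a:
            assert a[name].to_csv() == b[name].to_csv(), name

    def test_different_seeds_differ(self, small_config):
        other = small_config.model_copy(update={"seed": small_config.seed + 1})
        a = synthetic.generate_all(small_config)
        b = synthetic.generate_all(other)
        assert any(not a[n].equals(b[n]) for n in a)

    def test_one_variant_per_participant(self, small_config):
        participants, calls = synthetic.generate_cohort(small_config)
        per = calls.groupby("participant_id")["rsid"].nunique()
        assert (per == 1).all()

    def test_dual_carrier_flag(self):
        cfg = SimulationConfig(n_recalled=2, n_controls=2, seed=5, dual_carrier=True)
        _, calls = synthetic.generate_cohort(cfg)
        genes = calls[calls["participant_id"] == "P00000"]["gene"].nunique()
        assert genes == 2


class TestDiagnoses:
    def test_degenerate_probabilities(self):
        one = GroupRates(recalled=1.0, control=1.0)
        cfg = SimulationConfig(n_recalled=5, n_controls=5, p_e78=one, p_e780=one, seed=2)
        participants, _ = synthetic.generate_cohort(cfg)
        diagnoses = synthetic.generate_diagnoses(participants, cfg)
        e78 = diagnoses[diagnoses["icd10"].str.startswith("E78")]
        assert e78["participant_id"].nunique() == 10

        zero = GroupRates(recalled=0.0, control=0.0)
        cfg0 = cfg.model_copy(update={"p_e78": zero, "p_e780": zero})
        d0 = synthetic.generate_diagnoses(participants, cfg0)
        assert not d0["icd10"].str.startswith("E78").any()

    def test_prevalence_within_three_binomial_se(self):
        cfg = SimulationConfig(n_recalled=2, n_controls=2000, seed=13)
        participants, _ = synthetic.generate_cohort(cfg)
        diagnoses = synthetic.generate_diagnoses(participants, cfg)
        controls = participants[participants["group"] == "CONTROL"]["participant_id"]
        e78 = diagnoses[diagnoses["icd10"].str.startswith("E78")]["participant_id"].unique()
        rate = pd.Series(controls).isin(e78).mean()
        p = cfg.p_e78.control
        se = math.sqrt(p * (1 - p) / len(controls))
        assert abs(rate - p) < 3 * se

    def test_dates_inside_followup_window(self, small_config):
        participants, _ = synthetic.generate_cohort(small_config)
        diagnoses = synthetic.generate_diagnoses(participants, small_config)
        assert diagnoses["date"].min() >= small_config.followup_start
        assert diagnoses["date"].max() <= small_config.followup_end

    def test_no_z_codes_unless_flagged(self, small_config):
        participants, _ = synthetic.generate_cohort(small_config)
        diagnoses = synthetic.generate_diagnoses(participants, small_config)
        assert not diagnoses["icd10"].str.startswith("Z").any()
        flagged = small_config.model_copy(update={"include_z_codes": True})
        withz = synthetic.generate_diagnoses(participants, flagged)
        assert withz["icd10"].str.startswith("Z").any()


class TestPrescriptions:
    def test_no_users_when_p_llt_zero(self, small_config):
        zero = small_config.model_copy(
            update={"p_llt": GroupRates(recalled=0.0, control=0.0)}
        )
        participants, _ = synthetic.generate_cohort(zero)
        rx = synthetic.generate_prescriptions(participants, zero)
        assert len(rx) == 0

    def test_purchase_dates_inside_followup(self, default_config):
        participants, _ = synthetic.generate_cohort(default_config)
        rx = synthetic.generate_prescriptions(participants, default_config)
        assert rx["purchase_date"].min() >= default_config.followup_start
        assert rx["purchase_date"].max() < default_config.followup_end

    def test_archetype_round_trip(self, default_config):
        participants, _ = synthetic.generate_cohort(default_config)
        rx, intended = synthetic.generate_prescriptions(
            participants, default_config, with_archetypes=True
        )
        visits = participants.set_index("participant_id")["visit_date"].to_dict()
        observed = classify_cohort(rx, visits, default_config.followup_end)
        merged = observed.merge(intended, on="participant_id", validate="one_to_one")
        agreement = (merged["adherence_class"] == merged["archetype"]).mean()
        assert agreement >= 0.95
        # the three labels partition the user cohort
        assert set(merged["adherence_class"]) <= {
            "POOR", "CONSISTENT_POST_VISIT", "PRIOR_CONSISTENT_TERMINATED"
        }

    def test_consistent_archetype_covers_visit_to_followup_end(self):
        cfg = SimulationConfig(
            n_recalled=12, n_controls=1, seed=21,
            p_llt=GroupRates(recalled=1.0, control=0.0),
            archetype_mix=(0.0, 1.0, 0.0),
        )
        participants, _ = synthetic.generate_cohort(cfg)
        rx, intended = synthetic.generate_prescriptions(
            participants, cfg, with_archetypes=True
        )
        from fhrecall.adherence import build_supply_intervals, merge_into_episodes, records_from_frame

        visits = participants.set_index("participant_id")["visit_date"]
        for pid, recs in records_from_frame(rx).items():
            episodes = merge_into_episodes(build_supply_intervals(recs), 183)
            visit = visits[pid]
            covering = [
                ep for ep in episodes
                if (ep.start <= visit < ep.end) or 0 <= (ep.start - visit).days <= 365
            ]
            assert covering, pid
            assert any((cfg.followup_end - ep.end).days <= 183 for ep in covering), pid


class TestPgxAndSurvey:
    def test_degenerate_allele_frequencies(self, small_config):
        participants, _ = synthetic.generate_cohort(small_config)
        zero = small_config.model_copy(update={"pgx_risk_allele_freq": 0.0})
        assert (synthetic.generate_pgx_genotypes(participants, zero)["risk_allele_count"] == 0).all()
        one = small_config.model_copy(update={"pgx_risk_allele_freq": 1.0})
        assert (synthetic.generate_pgx_genotypes(participants, one)["risk_allele_count"] == 2).all()

    def test_hardy_weinberg_heterozygote_fraction(self):
        cfg = SimulationConfig(n_recalled=1, n_controls=10_000, seed=17)
        participants, _ = synthetic.generate_cohort(cfg)
        counts = synthetic.generate_pgx_genotypes(participants, cfg)["risk_allele_count"]
        het = (counts == 1).mean()
        expected = 2 * 0.16 * 0.84  # 0.2688
        se = math.sqrt(expected * (1 - expected) / len(counts))
        assert abs(het - expected) < 3 * se

    def test_full_response_when_nonresponse_zero(self, small_config):
        cfg = small_config.model_copy(update={"nonresponse_rate": 0.0})
        participants, _ = synthetic.generate_cohort(cfg)
        recalled = participants[participants["group"] == "RECALLED"]
        sv = synthetic.generate_survey(recalled, cfg)
        assert sv["participant_id"].nunique() == len(recalled)
        assert (sv.groupby("participant_id").size() == 40).all()

    def test_degenerate_item_distribution_gives_mean_five(self, small_config):
        cfg = small_config.model_copy(update={"nonresponse_rate": 0.0})
        participants, _ = synthetic.generate_cohort(cfg)
        recalled = participants[participants["group"] == "RECALLED"]
        sv = synthetic.generate_survey(recalled, cfg, item_distributions={"Q01": {"agree": 1.0}})
        from fhrecall.survey import item_means

        means = item_means(sv).set_index("item_id")
        assert means.loc["Q01", "item_mean"] == 5.0

    def test_bad_distribution_rejected(self, small_config):
        participants, _ = synthetic.generate_cohort(small_config)
        recalled = participants[participants["group"] == "RECALLED"]
        with pytest.raises(ValueError, match="sums to"):
            synthetic.generate_survey(
                recalled, small_config, item_distributions={"Q01": {"agree": 0.5}}
            )

    def test_nonresponse_binomial_expectation(self):
        cfg = SimulationConfig(n_recalled=32, n_controls=1, seed=29)
        participants, _ = synthetic.generate_cohort(cfg)
        recalled = participants[participants["group"] == "RECALLED"]
        sv = synthetic.generate_survey(recalled, cfg)
        returned = sv["participant_id"].nunique()
        se = math.sqrt(32 * 0.75 * 0.25)
        assert abs(returned - 24) <= 3 * se
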