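"""Synthetic-trial engine: patient generation, trial conduct, OC tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import obdesign as od
from obdesign.simulate import SimulationError
from conftest import category_probs


def _scenario(**kwargs) -> od.Scenario:
    probs = np.array(
        [
            category_probs(0.20, 0.05),
            category_probs(0.75, 0.15),
            category_probs(0.40, 0.45),
            category_probs(0.30, 0.60),
        ]
    )
    return od.Scenario(category_probs=probs, **kwargs)


def _design(**overrides) -> od.DesignParams:
    base = dict(
        n_doses=4,
        cohort_size=3,
        max_n=27,
        rule=od.AdmissibilityRule(0.35, 0.25),
        spec=od.UtilitySpec(od.DEFAULT_SCORES),
    )
    base.update(overrides)
    return od.DesignParams(**base)


class TestGeneratePatient:
    def test_no_ice_degenerate(self):
        sc = _scenario()
        rec = od.generate_patient(2, sc, np.random.default_rng(0))
        assert rec.events == ()
        ye, yt = rec.counterfactual
        obs_ye = int(any(o.efficacy for o in rec.observations))
        obs_yt = int(any(o.toxicity for o in rec.observations))
        assert (obs_ye, obs_yt) == (ye, yt)

    def test_point_mass_truth(self):
        probs = np.array([[0, 0, 0, 1.0]] * 2)
        sc = od.Scenario(category_probs=probs)
        rng = np.random.default_rng(1)
        for _ in range(20):
            rec = od.generate_patient(1, sc, rng)
            assert rec.counterfactual == (1, 0)

    def test_category_frequencies_match_truth(self):
        sc = _scenario()
        rng = np.random.default_rng(123)
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            rec = od.generate_patient(2, sc, rng)
            ye, yt = rec.counterfactual
            counts[od.DEFAULT_CODING.index_for(ye, yt) - 1] += 1
        p = sc.category_probs[1]
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(counts / n - p) <= 3 * se + 1e-12).all()

    def test_latent_strata_recorded_per_ice_type(self):
        sc = _scenario(
            ice_probs={"discontinuation_toxicity": 1.0, "death": 0.0}
        )
        rec = od.generate_patient(1, sc, np.random.default_rng(2))
        assert rec.latent_stratum == {"discontinuation_toxicity": True, "death": False}
        assert [e.type for e in rec.events] == ["discontinuation_toxicity"]
        assert all(0 < e.time <= sc.assess_window for e in rec.events)

    def test_death_truncates_observations(self):
        sc = _scenario(ice_probs={"death": 1.0}, ice_time_mean={"death": 5.0})
        rng = np.random.default_rng(3)
        for _ in range(50):
            rec = od.generate_patient(4, sc, rng)
            death_time = rec.events[0].time
            assert all(o.time <= death_time for o in rec.observations)
            assert len(rec.observations) >= 1


class TestRunTrial:
    def test_engine_contracts(self):
        sc = _scenario(ice_probs={"discontinuation_toxicity": 0.2})
        design = _design(accelerated_titration=True, titration_trigger_dose=3)
        res = od.run_trial(design, sc, od.case_study_strategies(), seed=11)
        assert res.n_enrolled <= design.max_n
        assert res.n_per_dose.sum() == res.n_enrolled
        assert (res.n_per_dose <= design.per_dose_cap).all()
        assert sum(c.n_total for c in res.final_counts.values()) <= res.n_enrolled
        if res.obd is not None:
            assert res.obd in res.admissible_final.doses
            assert res.obd <= res.mtd

    def test_reproducible_given_seed(self):
        sc = _scenario(ice_probs={"discontinuation_toxicity": 0.2})
        design = _design()
        a = od.run_trial(design, sc, od.case_study_strategies(), seed=5)
        b = od.run_trial(design, sc, od.case_study_strategies(), seed=5)
        assert a.assignment_history == b.assignment_history
        assert a.obd == b.obd and a.mtd == b.mtd

    def test_dominant_dose_always_selected(self):
        # dose 2 is a sure thing, the rest toxic or futile
        probs = np.array(
            [
                category_probs(0.02, 0.02),  # futile
                [0, 0, 0, 1.0],              # perfect
                category_probs(0.30, 0.80),  # toxic
                category_probs(0.30, 0.90),  # toxic
            ]
        )
        sc = od.Scenario(category_probs=probs)
        design = _design(max_n=36, per_dose_cap=36)
        for seed in range(10):
            res = od.run_trial(design, sc, od.case_study_strategies(), seed=seed)
            assert res.obd == 2

    def test_all_toxic_scenario_terminates_early(self):
        probs = np.array([category_probs(0.3, 0.95)] * 4)
        sc = od.Scenario(category_probs=probs)
        design = _design(max_n=60, per_dose_cap=60)
        n_term = sum(
            od.run_trial(design, sc, od.case_study_strategies(), seed=s).terminated_early
            for s in range(10)
        )
        assert n_term >= 9

    def test_toxicity_mode_requires_boundaries(self):
        with pytest.raises(SimulationError):
            _design(mode="toxicity_boin")

    def test_toxicity_mode_runs_boin_escalation(self):
        sc = _scenario()
        design = _design(mode="toxicity_boin", boundaries=od.boin_boundaries(0.30))
        res = od.run_trial(design, sc, od.case_study_strategies(), seed=2)
        assert res.obd is None and 1 <= res.mtd <= 4
        # interval moves: consecutive cohorts never jump more than one level
        doses = [d for _, d in res.assignment_history]
        assert all(abs(b - a) <= 1 for a, b in zip(doses, doses[1:]))

    def test_untried_doses_open_one_level_at_a_time(self):
        sc = _scenario()
        design = _design()
        res = od.run_trial(design, sc, od.case_study_strategies(), seed=8)
        seen_max = 0
        for _, dose in res.assignment_history:
            assert dose <= seen_max + 1
            seen_max = max(seen_max, dose)


class TestOperatingCharacteristics:
    def test_same_seed_identical_tables(self):
        sc = _scenario(ice_probs={"discontinuation_toxicity": 0.15})
        design = _design()
        a = od.operating_characteristics(design, sc, od.case_study_strategies(), 10, seed=3)
        b = od.operating_characteristics(design, sc, od.case_study_strategies(), 10, seed=3)
        pd.testing.assert_frame_equal(a.by_dose, b.by_dose)
        assert a.early_termination_pct == b.early_termination_pct

    def test_outcome_partition_sums_to_100(self):
        sc = _scenario()
        design = _design()
        oc = od.operating_characteristics(design, sc, od.case_study_strategies(), 25, seed=4)
        total = oc.selection_pct.sum() + oc.early_termination_pct
        assert total == pytest.approx(100.0)

    def test_dominant_dose_has_highest_selection(self):
        probs = np.array(
            [
                category_probs(0.10, 0.05),
                category_probs(0.75, 0.10),
                category_probs(0.35, 0.50),
                category_probs(0.30, 0.65),
            ]
        )
        sc = od.Scenario(category_probs=probs)
        design = _design()
        oc = od.operating_characteristics(design, sc, od.case_study_strategies(), 60, seed=9)
        assert int(oc.by_dose["selection_pct"].idxmax()) == 2


class TestPretabulate:
    def test_boin_rows_for_cohorts_of_three(self):
        design = _design(mode="toxicity_boin", boundaries=od.boin_boundaries(0.30, 0.18, 0.42))
        table = od.pretabulate_decisions(design, 3)
        row3 = table[table.n_at_dose == 3].set_index("dlt_count")["decision"]
        assert list(row3.loc[[0, 1, 2, 3]]) == [
            "escalate", "stay", "de_escalate", "de_escalate"
        ]
        one = table[(table.n_at_dose == 1) & (table.dlt_count == 0)]
        assert one["decision"].item() == "escalate"

    def test_toxicity_table_size(self):
        design = _design(mode="toxicity_boin", boundaries=od.boin_boundaries(0.30))
        assert len(od.pretabulate_decisions(design, 6)) == sum(n + 1 for n in range(1, 7))

    def test_utility_mode_enumerates_admissibility_flags(self):
        table = od.pretabulate_decisions(_design(), 3)
        # one row per count configuration: sum over n of C(n+3, 3)
        assert len(table) == 4 + 10 + 20
        # three toxic non-responders of three: posterior tail mass above
        # phi_t = 0.35 exceeds delta_t, so the dose is flagged toxic
        worst = table[(table.n_cat1 == 3) & (table.n_at_dose == 3)]
        assert worst["toxic"].item() and not worst["admissible"].item()

    def test_combinatorial_cap(self):
        with pytest.raises(SimulationError, match="cap"):
            od.pretabulate_decisions(_design(max_n=200, per_dose_cap=150), 150)
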