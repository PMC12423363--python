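"""ICE-handling strategies: resolution, tabulation, comparison, tipping point."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import obdesign as od
from obdesign.estimand import EstimandError


def _cfg(**overrides) -> od.StrategyConfig:
    base = od.case_study_strategies()
    for ice_type, strategy in overrides.items():
        base = base.with_strategy(ice_type, strategy)
    return base


class TestResolveOutcome:
    """The discontinuation trajectory: stable disease with toxicity at the
    day-30 discontinuation, complete response at the day-90 follow-up."""

    def test_treatment_policy_keeps_post_discontinuation_response(self, fig2_record):
        c = od.resolve_outcome(fig2_record, _cfg(discontinuation_toxicity="treatment_policy"))
        assert c.included and c.category == 3  # (Ye, Yt) = (1, 1)

    def test_while_on_treatment_stops_at_event_time(self, fig2_record):
        c = od.resolve_outcome(fig2_record, _cfg(discontinuation_toxicity="while_on_treatment"))
        assert c.included and c.category == 1  # only SD+toxicity by day 30

    def test_composite_imputes_lowest_utility_category(self, fig2_record):
        c = od.resolve_outcome(fig2_record, _cfg(discontinuation_toxicity="composite"))
        assert c.included and c.category == 1

    def test_no_events_identity(self):
        rec = od.PatientRecord("p", 1, observations=(od.Observation(10, 1, 0),))
        c = od.resolve_outcome(rec, od.case_study_strategies())
        assert c.included and c.category == 4

    def test_same_time_observation_included_under_while_on_treatment(self):
        rec = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(30.0, 1, 0),),
            events=(od.ICEvent("additional_therapy", 30.0),),
        )
        c = od.resolve_outcome(rec, _cfg(additional_therapy="while_on_treatment"))
        assert c.category == 4

    def test_event_after_recorded_response_is_not_decisive(self):
        # response achieved on day 20; discontinuation on day 40 is no ICE
        rec = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(20, 1, 0),),
            events=(od.ICEvent("discontinuation_toxicity", 40),),
        )
        c = od.resolve_outcome(rec, _cfg(discontinuation_toxicity="composite"))
        assert c.category == 4  # composite never fires

    def test_hypothetical_requires_counterfactual(self):
        rec = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(10, 0, 0),),
            events=(od.ICEvent("surgery_external", 5),),
        )
        with pytest.raises(EstimandError, match="counterfactual"):
            od.resolve_outcome(rec, od.case_study_strategies())
        with_cf = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(10, 0, 0),),
            events=(od.ICEvent("surgery_external", 5),),
            counterfactual=(1, 0),
        )
        assert od.resolve_outcome(with_cf, od.case_study_strategies()).category == 4

    def test_principal_stratum_excludes_would_experience(self):
        cfg = _cfg(ada_occurrence="principal_stratum")
        rec = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(10, 1, 0),),
            events=(od.ICEvent("ada_occurrence", 5),),
            latent_stratum={"ada_occurrence": True},
        )
        c = od.resolve_outcome(rec, cfg)
        assert not c.included and c.category is None
        no_stratum = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(10, 1, 0),),
            events=(od.ICEvent("ada_occurrence", 5),),
        )
        with pytest.raises(EstimandError, match="stratum"):
            od.resolve_outcome(no_stratum, cfg)

    def test_unmapped_event_type_errors(self):
        cfg = od.StrategyConfig({"death": "composite"}, precedence=("death",))
        rec = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(10, 0, 0),),
            events=(od.ICEvent("nonadherence", 3),),
        )
        with pytest.raises(EstimandError, match="nonadherence"):
            od.resolve_outcome(rec, cfg)

    def test_composite_without_toxicity_type_keeps_observed_yt(self):
        rec = od.PatientRecord(
            "p", 1,
            observations=(od.Observation(10, 0, 0),),
            events=(od.ICEvent("progression_discontinuation", 15),),
        )
        c = od.resolve_outcome(rec, od.case_study_strategies())
        assert c.category == 2  # failure, but no toxicity forced

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(perm=st.permutations(range(3)))
    def test_event_list_order_never_matters(self, perm):
        events = (
            od.ICEvent("additional_therapy", 12.0),
            od.ICEvent("discontinuation_toxicity", 25.0),
            od.ICEvent("dose_switch", 5.0),
        )
        shuffled = tuple(events[i] for i in perm)
        obs = (od.Observation(20, 0, 1), od.Observation(50, 1, 0))
        a = od.resolve_outcome(
            od.PatientRecord("p", 1, observations=obs, events=events),
            od.case_study_strategies(),
        )
        b = od.resolve_outcome(
            od.PatientRecord("p", 1, observations=obs, events=shuffled),
            od.case_study_strategies(),
        )
        assert (a.included, a.category) == (b.included, b.category)


class TestTabulate:
    def test_counting(self):
        recs = [
            od.PatientRecord("a", 2, observations=(od.Observation(10, 1, 0),)),
            od.PatientRecord("b", 2, observations=(od.Observation(10, 1, 0),)),
            od.PatientRecord("c", 2, observations=(od.Observation(10, 0, 1),)),
        ]
        tab = od.tabulate(recs, od.case_study_strategies())
        np.testing.assert_array_equal(tab.counts_for(2).counts, [1, 0, 0, 2])

    def test_exclusions_conserve_total(self):
        cfg = _cfg(ada_occurrence="principal_stratum")
        recs = [
            od.PatientRecord(
                "a", 1,
                observations=(od.Observation(10, 1, 0),),
                events=(od.ICEvent("ada_occurrence", 5),),
                latent_stratum={"ada_occurrence": True},
            ),
            od.PatientRecord("b", 1, observations=(od.Observation(10, 0, 0),)),
            od.PatientRecord("c", 1, observations=(od.Observation(10, 1, 0),)),
        ]
        tab = od.tabulate(recs, cfg)
        assert tab.n_included == 2 and len(tab.exclusions) == 1
        assert tab.n_included + len(tab.exclusions) == len(recs)

    def test_empty_records_give_zero_counts(self):
        tab = od.tabulate([], od.case_study_strategies(), n_doses=2)
        assert tab.counts_for(1).n_total == 0 and tab.counts_for(2).n_total == 0


def _ice_fixture(n_doses: int = 3, per_dose: int = 4) -> list[od.PatientRecord]:
    """Every ICE'd patient later responds: composite must not beat policy."""
    recs = []
    for j in range(1, n_doses + 1):
        for i in range(per_dose):
            if i % 2 == 0:
                recs.append(
                    od.PatientRecord(
                        f"d{j}i{i}", j,
                        observations=(od.Observation(30, 0, 1), od.Observation(60, 1, 0)),
                        events=(od.ICEvent("discontinuation_toxicity", 30),),
                    )
                )
            else:
                recs.append(
                    od.PatientRecord(f"d{j}i{i}", j, observations=(od.Observation(20, 1, 0),))
                )
    return recs


class TestCompareEstimands:
    def test_identical_configs_identical_rows(self, default_spec, vague_prior, rule):
        recs = _ice_fixture()
        cfg = od.case_study_strategies()
        table = od.compare_estimands(
            recs, {"a": cfg, "b": cfg}, default_spec, vague_prior, rule
        )
        pd.testing.assert_series_equal(
            table.loc["a"], table.loc["b"], check_names=False
        )

    def test_treatment_policy_dominates_composite_on_responders(
        self, default_spec, vague_prior, rule
    ):
        recs = _ice_fixture()
        table = od.compare_estimands(
            recs,
            {
                "policy": _cfg(discontinuation_toxicity="treatment_policy"),
                "composite": _cfg(discontinuation_toxicity="composite"),
            },
            default_spec, vague_prior, rule,
        )
        for j in (1, 2, 3):
            col = f"utility_dose_{j}"
            assert table.loc["policy", col] >= table.loc["composite", col]

    def test_no_ice_records_make_all_strategies_agree(
        self, default_spec, vague_prior, rule
    ):
        recs = [
            od.PatientRecord(f"p{i}", 1 + i % 2, observations=(od.Observation(10, i % 3 == 0, 0),))
            for i in range(8)
        ]
        configs = {
            s: od.StrategyConfig(
                {t: s for t in od.case_study_strategies().per_ice_strategy}
            )
            for s in ("treatment_policy", "composite", "while_on_treatment",
                      "hypothetical", "principal_stratum")
        }
        table = od.compare_estimands(recs, configs, default_spec, vague_prior, rule)
        utils = table[[c for c in table.columns if c.startswith("utility")]]
        assert (utils.nunique() == 1).all()


class TestTippingPoint:
    def _records(self, pending_ids=()):
        """Dose 1: three clean responders (posterior mean utility 85.625).
        Dose 2: five clean responders plus one with toxicity (86.07, a hair
        ahead; toxicity mean 0.214 keeps the MTD at dose 2).  Flipping one
        dose-2 responder to the worst category drops dose 2 to 71.8,
        handing the OBD to dose 1."""
        recs = []
        for i, (dose, ye, yt) in enumerate(
            [(1, 1, 0), (1, 1, 0), (1, 1, 0),
             (2, 1, 0), (2, 1, 0), (2, 1, 0), (2, 1, 0), (2, 1, 0), (2, 1, 1)]
        ):
            pid = f"p{i}"
            recs.append(
                od.PatientRecord(
                    pid, dose,
                    observations=(od.Observation(10, ye, yt),),
                    pending=pid in pending_ids,
                )
            )
        return recs

    def test_no_pending_records_keep_obd_constant(self, default_spec, vague_prior, rule):
        with pytest.warns(UserWarning, match="capped"):
            res = od.tipping_point(
                self._records(), od.case_study_strategies(), default_spec,
                vague_prior, rule, max_shift=3,
            )
        assert res.n_shiftable == 0 and res.tipping_shift is None
        assert res.table["obd"].nunique() == 1

    def test_utility_monotone_nonincreasing_in_shift(self, default_spec, vague_prior, rule):
        res = od.tipping_point(
            self._records(pending_ids={"p0", "p1", "p3"}),
            od.case_study_strategies(), default_spec, vague_prior, rule, max_shift=3,
        )
        for col in ("utility_dose_1", "utility_dose_2"):
            assert (np.diff(res.table[col]) <= 1e-9).all()

    def test_single_flip_tips_a_knife_edge_comparison(self, default_spec, vague_prior, rule):
        # dose 2 leads dose 1 by less than one flip's worth of utility
        recs = self._records(pending_ids={"p3"})
        base = od.tipping_point(
            recs, od.case_study_strategies(), default_spec, vague_prior, rule, max_shift=1
        )
        assert base.table.loc[0, "obd"] == 2
        assert base.tipping_shift == 1  # flipping p3 at dose 2 hands the OBD to dose 1

    def test_excess_max_shift_is_capped_with_warning(self, default_spec, vague_prior, rule):
        with pytest.warns(UserWarning, match="capped"):
            res = od.tipping_point(
                self._records(pending_ids={"p3"}),
                od.case_study_strategies(), default_spec, vague_prior, rule, max_shift=10,
            )
        assert res.table.index.max() == 1
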