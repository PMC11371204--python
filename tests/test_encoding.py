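import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rollrisk as rr
from rollrisk.encoding import (
    DemographicSpec,
    EncodingPlan,
    NumericSpec,
    assemble_design_matrix,
    encode_contemporaneous,
    encode_historical,
    encode_numeric_pair,
    encode_past_present,
    fit_encoding_plan,
)
from rollrisk.selection import ContingencyTable, PredictorDecision
from rollrisk.timeseries import _with_month

from conftest import START, adult, make_demo, make_events


def decision(code, category, retained=True):
    return PredictorDecision(
        code=code, category=category, table=ContingencyTable(1, 1, 1, 1),
        direction="risk", prc1_p=0.01, prc2_prob=0.99, retained=retained,
    )


class TestSeriesEncoders:
    def test_past_present_occurrence_mid_series(self):
        assert encode_past_present([2, 5, 9], [5]).tolist() == [0, 1, 1]

    def test_past_present_no_occurrence(self):
        assert encode_past_present([2, 5, 9], []).tolist() == [0, 0, 0]

    def test_past_present_first_row(self):
        assert encode_past_present([2, 5, 9], [2]).tolist() == [1, 1, 1]

    def test_hist_now_mid_series(self):
        assert encode_historical([2, 5, 9], [5]).tolist() == [0, 0, 1]
        assert encode_contemporaneous([2, 5, 9], [5]).tolist() == [0, 1, 0]

    def test_every_row_occurrence(self):
        months = [1, 2, 3, 4]
        assert encode_historical(months, months).tolist() == [0, 1, 1, 1]
        assert encode_contemporaneous(months, months).tolist() == [1, 1, 1, 1]

    @settings(max_examples=200, deadline=None)
    @given(
        rows=st.lists(st.integers(0, 30), min_size=1, max_size=10, unique=True),
        occ=st.lists(st.integers(0, 30), max_size=10),
    )
    def test_pp_equals_hist_or_now(self, rows, occ):
        rows = sorted(rows)
        pp = encode_past_present(rows, occ)
        hist = encode_historical(rows, occ)
        now = encode_contemporaneous(rows, occ)
        assert (pp == (hist | now)).all()
        # hist is the running max of prior-row `now` plus non-row occurrences:
        # it never decreases and implies pp
        assert (np.diff(hist) >= 0).all()


class TestNumericPair:
    SPEC = NumericSpec("X", trim_low=0.0, trim_high=10.0, mean=5.0, sd=2.0)

    def test_absent_measurement_sits_at_mean(self):
        pn, vn, ph, vh = encode_numeric_pair([3, 4], {}, self.SPEC)
        assert pn.tolist() == [0, 0] and vn.tolist() == [0.0, 0.0]
        assert ph.tolist() == [0, 0] and vh.tolist() == [0.0, 0.0]

    def test_running_max_keeps_higher_value(self):
        pn, vn, ph, vh = encode_numeric_pair([2, 5, 9], {2: 7.0, 5: 5.0}, self.SPEC)
        assert vn.tolist() == [1.0, 0.0, 0.0]
        assert vh.tolist() == [0.0, 1.0, 1.0]  # standardized(7) = 1
        assert ph.tolist() == [0, 1, 1]

    def test_clipping_above_upper_percentile(self):
        _, vn, _, _ = encode_numeric_pair([1], {1: 99.0}, self.SPEC)
        _, vn_at, _, _ = encode_numeric_pair([1], {1: 10.0}, self.SPEC)
        assert vn.tolist() == vn_at.tolist()


class TestPlanFitting:
    def _cohort(self):
        ev = make_events(
            [
                ("p1", "encounter", "ENC", 0),
                ("p1", "encounter", "ENC", 6),
                ("p1", "vital", "BMI", 0, 30.0),
                ("p2", "encounter", "ENC", 0),
                ("p2", "vital", "BMI", 0, 20.0),
                ("p2", "encounter", "ENC", 3),
                ("p2", "diagnosis", "DXA", 3),
            ]
        )
        demo = make_demo(
            [
                adult("p1"), adult("p2"),
                ("p1", "sex", "F"), ("p2", "sex", "M"),
                ("p1", "smoker", "never"),
            ]
        )
        rows = rr.build_patient_months(ev, pd.Index(["p1", "p2"]))
        rows["outcome"] = pd.array([0] * len(rows), dtype="Int8")
        return ev, demo, rows

    def test_constants_come_from_analytic_rows_only(self):
        ev, demo, rows = self._cohort()
        plan = fit_encoding_plan(rows, ev, demo, [decision("DXA", "diagnosis")])
        np.testing.assert_allclose(plan.numeric_specs[0].mean, 25.0)
        # leakage guard: adding later months must not move any constant
        ev_extra = pd.concat(
            [ev, make_events([("p1", "encounter", "ENC", 20), ("p1", "vital", "BMI", 20, 60.0)])],
            ignore_index=True,
        )
        plan2 = fit_encoding_plan(rows, ev_extra, demo, [decision("DXA", "diagnosis")])
        assert plan.to_json() == plan2.to_json()

    def test_zero_variance_numeric_dropped_with_warning(self):
        ev, demo, rows = self._cohort()
        ev.loc[ev["code"] == "BMI", "numeric_value"] = 22.0
        with pytest.warns(UserWarning, match="zero analytic variance"):
            plan = fit_encoding_plan(rows, ev, demo, [])
        assert all(s.name != "BMI" for s in plan.numeric_specs)

    def test_plan_json_roundtrip(self):
        ev, demo, rows = self._cohort()
        plan = fit_encoding_plan(rows, ev, demo, [decision("DXA", "diagnosis")])
        assert EncodingPlan.from_json(plan.to_json()) == plan


class TestColumnCounting:
    def test_counting_rule_3dx_2med_1lab_age(self):
        plan = EncodingPlan(
            diagnosis_codes=("D1", "D2", "D3"),
            other_binary_codes=(("L1", "lab"), ("M1", "medication"), ("M2", "medication")),
            numeric_specs=(),
            row_numeric_specs=(),
            demographic_specs=(),
        )
        # 3 pp + 3x2 hist/now + age = 10
        assert len(plan.column_names) == 10

    def test_numeric_contributes_four(self):
        plan = EncodingPlan(numeric_specs=(NumericSpec("BMI", 0, 1, 0.5, 1.0),))
        assert len(plan.column_names) == 4 + 1  # + age

    def test_duplicate_columns_rejected(self):
        plan = EncodingPlan(diagnosis_codes=("D1", "D1"))
        with pytest.raises(ValueError, match="duplicate"):
            plan.column_names


class TestAssembledMatrix:
    @pytest.fixture(scope="class")
    def assembled(self, small_cohort):
        cfg, events, demo, _ = small_cohort
        spec = rr.CohortSpec()
        eligible = rr.apply_cohort_filters(events, demo, spec)
        rows = rr.build_patient_months(events, eligible)
        T = START + 33
        rows = rr.code_outcome(rows, events, spec, horizon_end=T - 1)
        analytic = rows[(rows["month_index"] <= T - 13) & rows["outcome"].notna()].reset_index(drop=True)
        decisions = rr.select_predictors(analytic, events, cohort_spec=spec, analytic_end=T - 13)
        plan = fit_encoding_plan(analytic, events, demo, decisions)
        X, y = assemble_design_matrix(analytic, events, demo, plan)
        return events, demo, analytic, plan, X, y

    def test_no_missing_cells_and_binary_domain(self, assembled):
        events, demo, analytic, plan, X, y = assembled
        assert not X.isna().any().any()
        for code in plan.diagnosis_codes:
            assert set(np.unique(X[f"{code}:pp"])) <= {0.0, 1.0}
        for code, _ in plan.other_binary_codes:
            assert set(np.unique(X[f"{code}:hist"])) <= {0.0, 1.0}
            assert set(np.unique(X[f"{code}:now"])) <= {0.0, 1.0}

    def test_analytic_age_standardized(self, assembled):
        *_, X, y = assembled
        assert abs(X["age"].mean()) < 1e-9
        assert abs(X["age"].std(ddof=0) - 1.0) < 1e-9

    def test_analytic_row_descriptors_standardized(self, assembled):
        *_, X, y = assembled
        for col in ("gap_months", "encounter_count"):
            assert abs(X[col].mean()) < 1e-9
            assert abs(X[col].std(ddof=0) - 1.0) < 1e-9

    def test_numeric_value_now_standardized_over_measured(self, assembled):
        events, demo, analytic, plan, X, y = assembled
        for spec in plan.numeric_specs:
            measured = X[f"{spec.name}:present_now"] == 1.0
            vals = X.loc[measured, f"{spec.name}:value_now"]
            assert abs(vals.mean()) < 1e-9
            assert abs(vals.std(ddof=0) - 1.0) < 1e-9

    def test_pp_matches_hist_or_now_reference(self, assembled):
        """Recompute all three schemas per patient via the reference encoders."""
        events, demo, analytic, plan, X, y = assembled
        ev = _with_month(events)
        codes = list(plan.diagnosis_codes)[:5]
        for code in codes:
            occ = ev.loc[ev["code"] == code].groupby("patient_id")["month_index"].agg(list)
            for pid, grp in analytic.groupby("patient_id"):
                months = grp["month_index"].tolist()
                o = occ.get(pid, [])
                pp_ref = encode_past_present(months, o)
                both = encode_historical(months, o) | encode_contemporaneous(months, o)
                got = X.loc[(pid,), f"{code}:pp"].to_numpy()
                assert (got == pp_ref).all()
                assert (pp_ref == both).all()

    def test_hist_now_match_reference(self, assembled):
        events, demo, analytic, plan, X, y = assembled
        ev = _with_month(events)
        code, _cat = plan.other_binary_codes[0]
        occ = ev.loc[ev["code"] == code].groupby("patient_id")["month_index"].agg(list)
        for pid, grp in list(analytic.groupby("patient_id"))[:200]:
            months = grp["month_index"].tolist()
            o = occ.get(pid, [])
            assert (X.loc[(pid,), f"{code}:hist"].to_numpy() == encode_historical(months, o)).all()
            assert (X.loc[(pid,), f"{code}:now"].to_numpy() == encode_contemporaneous(months, o)).all()

    def test_encoding_is_pure(self, assembled):
        events, demo, analytic, plan, X, y = assembled
        X2, y2 = assemble_design_matrix(analytic, events, demo, plan)
        pd.testing.assert_frame_equal(X, X2)
        np.testing.assert_array_equal(y, y2)

    def test_age_increases_within_patient(self, assembled):
        *_, X, y = assembled
        multi = X.groupby(level="patient_id")["age"].agg(["count", lambda s: (np.diff(s) > 0).all()])
        multi = multi[multi["count"] > 1]
        assert multi.iloc[:, 1].all()


class TestDemographics:
    def _setup(self, demo_records, analytic_months=(0, 3, 6, 9)):
        ev = make_events([("p1", "encounter", "ENC", m) for m in analytic_months])
        demo = make_demo([adult("p1")] + demo_records)
        rows = rr.build_patient_months(ev, pd.Index(["p1"]))
        rows["outcome"] = pd.array([0] * len(rows), dtype="Int8")
        return ev, demo, rows

    def test_one_hot_plus_missing_partition(self):
        ev, demo, rows = self._setup([("p1", "smoker", "never")])
        plan = fit_encoding_plan(rows, ev, demo, [], demographic_attributes=("smoker",))
        X, _ = assemble_design_matrix(rows, ev, demo, plan)
        demo_cols = [c for c in X.columns if c.startswith("demo:smoker")]
        assert X[demo_cols].sum(axis=1).eq(1.0).all()

    def test_missing_indicator_when_absent(self):
        ev, demo, rows = self._setup([])
        plan = fit_encoding_plan(rows, ev, demo, [], demographic_attributes=("smoker",))
        X, _ = assemble_design_matrix(rows, ev, demo, plan)
        assert X["demo:smoker=__missing__"].eq(1.0).all()

    def test_time_invariant_constant_across_rows(self):
        ev, demo, rows = self._setup([("p1", "sex", "F")])
        plan = fit_encoding_plan(rows, ev, demo, [], demographic_attributes=("sex",))
        X, _ = assemble_design_matrix(rows, ev, demo, plan)
        assert X["demo:sex=F"].eq(1.0).all()

    def test_time_varying_flips_at_effective_month(self):
        from conftest import month_date

        ev, demo, rows = self._setup(
            [
                ("p1", "smoker", "current", month_date(0)),
                ("p1", "smoker", "never", month_date(6)),
            ]
        )
        plan = fit_encoding_plan(rows, ev, demo, [], demographic_attributes=("smoker",))
        X, _ = assemble_design_matrix(rows, ev, demo, plan)
        assert X["demo:smoker=current"].tolist() == [1.0, 1.0, 0.0, 0.0]
        assert X["demo:smoker=never"].tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_unseen_level_maps_to_missing_with_warning(self):
        ev, demo, rows = self._setup([("p1", "smoker", "never")])
        plan = fit_encoding_plan(rows, ev, demo, [], demographic_attributes=("smoker",))
        demo2 = demo.copy()
        demo2.loc[demo2["attribute"] == "smoker", "value"] = "vaper"
        with pytest.warns(UserWarning, match="unseen"):
            X, _ = assemble_design_matrix(rows, ev, demo2, plan)
        assert X["demo:smoker=__missing__"].eq(1.0).all()
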