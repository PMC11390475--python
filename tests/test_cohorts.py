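"""Case collection, time-models, sex filter and matched control selection."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caseforge import (
    CaseSet,
    TimeModelSpec,
    apply_sex_filter,
    apply_time_model,
    collect_cases,
    compute_time_lag,
    select_controls,
)
from caseforge.cohorts import potential_controls

HIER = pd.DataFrame({
    "code": ["N18", "N18.3", "N18.9", "N20", "E11"],
    "parent": ["", "N18", "N18", "", ""],
    "chapter": ["XIV", "XIV", "XIV", "XIV", "IV"],
})


def _participants(n, sex=None, age=None):
    return pd.DataFrame({
        "eid": np.arange(1, n + 1),
        "sex": sex if sex is not None else ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "age": age if age is not None else np.full(n, 55),
        "ancestry": ["EUR"] * n,
        "collection_date": pd.to_datetime(["2008-06-01"] * n),
    })


class TestTimeLag:
    def test_same_day_is_zero(self):
        assert compute_time_lag("2010-03-01", "2010-03-01") == 0

    def test_two_calendar_years(self):
        # 730 days / 365 = 2.0 exactly
        assert compute_time_lag("2010-01-01", "2012-01-01") == 2

    def test_negative_decade_with_leap_days(self):
        # 2005-06-01 .. 2015-06-01 spans leap days 2008 and 2012: 3,652 days
        days = (dt.date(2005, 6, 1) - dt.date(2015, 6, 1)).days
        assert days == -3652
        assert compute_time_lag("2015-06-01", "2005-06-01") == -10

    @given(delta=st.integers(min_value=-8000, max_value=8000))
    @settings(max_examples=200, deadline=None)
    def test_matches_round_half_away_from_zero_oracle(self, delta):
        coll = pd.Timestamp("2009-06-15")
        lag = compute_time_lag(coll, coll + pd.Timedelta(days=delta))
        import math

        years = delta / 365
        expected = int(math.copysign(math.floor(abs(years) + 0.5), years))
        assert lag == expected


class TestCollectCases:
    def test_subnode_diagnoses_count_for_parent(self, toy_participants):
        diag = pd.DataFrame({
            "eid": [1, 2],
            "icd10": ["N18.3", "N18.9"],
            "diag_date": pd.to_datetime(["2010-01-01", "2007-01-01"]),
            "source": ["hes", "hes"],
        })
        cs = collect_cases(diag, HIER, toy_participants, "N18")
        assert set(cs.case_ids) == {1, 2}

    def test_participant_in_two_sources_counted_once(self, toy_participants):
        diag = pd.DataFrame({
            "eid": [1, 1],
            "icd10": ["N18", "N18"],
            "diag_date": pd.to_datetime(["2010-01-01", "2010-01-01"]),
            "source": ["hes", "death"],
        })
        cs = collect_cases(diag, HIER, toy_participants, "N18")
        assert cs.n_cases == 1

    def test_shortest_absolute_lag_retained(self, toy_participants):
        # collection 2008-06-01: lags +2y (N18.3) and -4y (N18.9) -> keep +2
        diag = pd.DataFrame({
            "eid": [1, 1],
            "icd10": ["N18.3", "N18.9"],
            "diag_date": pd.to_datetime(["2010-06-01", "2004-06-01"]),
            "source": ["hes", "hes"],
        })
        cs = collect_cases(diag, HIER, toy_participants, "N18")
        assert cs.table["lag_years"].tolist() == [2]

    def test_unknown_code_raises(self, toy_participants):
        diag = pd.DataFrame({"eid": [1], "icd10": ["N18"],
                             "diag_date": pd.to_datetime(["2010-01-01"]),
                             "source": ["hes"]})
        with pytest.raises(KeyError):
            collect_cases(diag, HIER, toy_participants, "Z99")

    def test_ninety_nine_cases_not_eligible(self):
        n = 300
        parts = _participants(n)
        diag = pd.DataFrame({
            "eid": np.arange(1, 100),
            "icd10": ["N18"] * 99,
            "diag_date": pd.to_datetime(["2010-01-01"] * 99),
            "source": ["hes"] * 99,
        })
        cs = collect_cases(diag, HIER, parts, "N18")
        assert cs.n_cases == 99 and not cs.eligible


class TestTimeModel:
    def _case_set(self, lags):
        return CaseSet("N18", pd.DataFrame({"eid": np.arange(len(lags)),
                                            "lag_years": lags}))

    def test_time_agnostic_is_identity(self):
        cs = self._case_set([-12, -3, 0, 4, 11])
        out = apply_time_model(cs, TimeModelSpec("time-agnostic"))
        assert out.table["lag_years"].tolist() == [-12, -3, 0, 4, 11]

    def test_prognostic_inclusive_upper_bound(self):
        cs = self._case_set([-1, 0, 5, 10, 11])
        out = apply_time_model(cs, TimeModelSpec("prognostic", 10))
        assert out.table["lag_years"].tolist() == [0, 5, 10]

    def test_diagnostic_inclusive_lower_bound(self):
        cs = self._case_set([-11, -10, -1, 0, 3])
        out = apply_time_model(cs, TimeModelSpec("diagnostic", 10))
        assert out.table["lag_years"].tolist() == [-10, -1, 0]

    def test_prognostic_and_diagnostic_partition_overlaps_only_at_zero(self):
        lags = list(range(-15, 16))
        cs = self._case_set(lags)
        agn = set(apply_time_model(cs, TimeModelSpec("time-agnostic")).table["eid"])
        pro = set(apply_time_model(cs, TimeModelSpec("prognostic", 10)).table["eid"])
        dia = set(apply_time_model(cs, TimeModelSpec("diagnostic", 10)).table["eid"])
        assert pro | dia <= agn
        overlap_lags = cs.table.set_index("eid").loc[sorted(pro & dia), "lag_years"]
        assert (overlap_lags == 0).all()


class TestSexFilter:
    def _cases(self, n):
        return CaseSet("N18", pd.DataFrame({"eid": np.arange(1, n + 1),
                                            "lag_years": np.zeros(n, int)}))

    def test_dominant_sex_above_threshold_drops_minority(self):
        parts = _participants(100, sex=["F"] * 95 + ["M"] * 5)
        out = apply_sex_filter(self._cases(100), parts)
        assert out.sex_filtered
        sex = parts.set_index("eid").loc[out.case_ids, "sex"]
        assert (sex == "F").all() and out.n_cases == 95

    def test_breast_hypertrophy_like_ratio_unchanged(self):
        # 317 male / 864 female -> dominant proportion 0.732, below 0.9
        parts = _participants(1181, sex=["M"] * 317 + ["F"] * 864)
        out = apply_sex_filter(self._cases(1181), parts)
        assert not out.sex_filtered and out.n_cases == 1181

    def test_balanced_split_unchanged(self):
        parts = _participants(100, sex=["F"] * 60 + ["M"] * 40)
        out = apply_sex_filter(self._cases(100), parts)
        assert not out.sex_filtered and out.n_cases == 100


class TestSelectControls:
    def _setup(self, n_cases=100, n_pool=10_000):
        n = n_cases + n_pool
        rng = np.random.default_rng(0)
        parts = _participants(
            n,
            sex=list(rng.choice(["F", "M"], n)),
            age=rng.integers(40, 70, n),
        )
        diag = pd.DataFrame({
            "eid": np.arange(1, n_cases + 1),
            "icd10": ["N18"] * n_cases,
            "diag_date": pd.to_datetime(["2010-01-01"] * n_cases),
            "source": ["hes"] * n_cases,
        })
        cs = collect_cases(diag, HIER, parts, "N18")
        return parts, diag, cs

    def test_full_ratio_with_ample_supply(self):
        parts, diag, cs = self._setup()
        cohort = select_controls(cs, parts, diag, HIER, ctrl_ratio_max=19, seed=4)
        assert cohort.ctrl_ratio == 19
        assert len(cohort.control_ids) == 19 * len(cohort.case_ids)
        assert len(cohort.case_ids) == 100

    def test_same_chapter_diagnosis_excluded_from_controls(self):
        parts, diag, cs = self._setup()
        extra = pd.DataFrame({"eid": [200, 201], "icd10": ["N20", "N18.3"],
                              "diag_date": pd.to_datetime(["2009-01-01"] * 2),
                              "source": ["hes"] * 2})
        diag = pd.concat([diag, extra], ignore_index=True)
        pool = potential_controls(parts, diag, HIER, "N18")
        assert 200 not in pool and 201 not in pool
        cohort = select_controls(cs, parts, diag, HIER, ctrl_ratio_max=9, seed=4)
        assert 200 not in cohort.control_ids and 201 not in cohort.control_ids

    def test_per_cell_matching_is_exact(self):
        parts, diag, cs = self._setup()
        cohort = select_controls(cs, parts, diag, HIER, ctrl_ratio_max=9, seed=4)
        info = parts.set_index("eid")
        edges = cohort.age_bin_edges

        def cells(ids):
            age = info.loc[ids, "age"].to_numpy(float)
            sex = info.loc[ids, "sex"].to_numpy()
            b = np.clip(np.searchsorted(edges, age, side="right") - 1,
                        0, edges.size - 2)
            out = {}
            for bb, ss in zip(b, sex):
                out[(bb, ss)] = out.get((bb, ss), 0) + 1
            return out

        case_cells = cells(cohort.case_ids)
        ctrl_cells = cells(cohort.control_ids)
        for cell, n_cases in case_cells.items():
            assert ctrl_cells.get(cell, 0) == cohort.ctrl_ratio * n_cases

    def test_cases_and_controls_disjoint(self):
        parts, diag, cs = self._setup()
        cohort = select_controls(cs, parts, diag, HIER, ctrl_ratio_max=9, seed=4)
        assert not set(cohort.case_ids) & set(cohort.control_ids)

    def test_deterministic_given_seed(self):
        parts, diag, cs = self._setup()
        c1 = select_controls(cs, parts, diag, HIER, ctrl_ratio_max=9, seed=4)
        c2 = select_controls(cs, parts, diag, HIER, ctrl_ratio_max=9, seed=4)
        assert np.array_equal(c1.control_ids, c2.control_ids)

    def test_no_potential_controls_raises(self):
        parts = _participants(120)
        diag = pd.DataFrame({
            "eid": np.arange(1, 121),
            "icd10": ["N18"] * 120,
            "diag_date": pd.to_datetime(["2010-01-01"] * 120),
            "source": ["hes"] * 120,
        })
        cs = collect_cases(diag, HIER, parts, "N18")
        with pytest.raises(ValueError):
            select_controls(cs, parts, diag, HIER, seed=0)
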