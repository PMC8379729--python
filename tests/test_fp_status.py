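"""Unit and property tests for the DFPS classification rules."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fpequity.fp_status import (
    LARC_METHODS,
    PERMANENT_METHODS,
    SARC_METHODS,
    assess_fecundity,
    assess_need,
    classify_method,
    classify_table,
    dfps_flags,
)
from fpequity.io_model import METHODS

from conftest import make_record
from oracles import oracle_fecundity, oracle_need


class TestClassifyMethod:
    @pytest.mark.parametrize(
        "method,modernity,action",
        [
            ("iud", "modern", "LARC"),
            ("female_sterilization", "modern", "PERMANENT"),
            ("male_sterilization", "modern", "PERMANENT"),
            ("pill", "modern", "SARC"),
            ("emergency", "modern", "SARC"),
            ("traditional", "traditional", "not_applicable"),
            ("none", "none", "not_applicable"),
        ],
    )
    def test_examples(self, method, modernity, action):
        mc = classify_method(method)
        assert (mc.modernity, mc.action_class) == (modernity, action)

    def test_partition_matches_canonical_lists(self):
        """The preimages of SARC/LARC/PERMANENT are exactly the three
        published method lists."""
        got = {"SARC": set(), "LARC": set(), "PERMANENT": set()}
        for m in METHODS:
            if m == "other_modern":
                continue  # configurable residual category
            mc = classify_method(m)
            if mc.modernity == "modern":
                got[mc.action_class].add(m)
            else:
                assert mc.action_class == "not_applicable"
        assert got["SARC"] == set(SARC_METHODS)
        assert got["LARC"] == set(LARC_METHODS)
        assert got["PERMANENT"] == set(PERMANENT_METHODS)

    def test_other_modern_is_configurable(self):
        assert classify_method("other_modern", "SARC").action_class == "SARC"
        assert classify_method("other_modern", "LARC").action_class == "LARC"
        assert classify_method("other_modern").modernity == "modern"

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError, match="unknown contraceptive method"):
            classify_method("implant")


class TestFecundity:
    def test_long_union_without_use_or_pregnancy(self):
        r = make_record(years_in_union=7, used_contraception_past_5y=False,
                        pregnant_in_past_5y=False)
        assert assess_fecundity(r) == ("infecund", "rule1_union5y")

    def test_amenorrhea_over_six_months(self):
        r = make_record(months_since_last_period=8.0, postpartum_amenorrheic=False)
        assert assess_fecundity(r) == ("infecund", "rule4_amenorrhea6m")

    def test_pregnancy_demonstrates_fecundity(self):
        r = make_record(currently_pregnant=True, self_reported_infecund=True,
                        pregnancy_wantedness="wanted_then")
        assert assess_fecundity(r) == ("fecund", None)

    def test_six_months_boundary_is_fecund(self):
        r = make_record(months_since_last_period=6.0)
        assert assess_fecundity(r)[0] == "fecund"

    def test_all_rule_inputs_missing_is_indeterminate(self):
        r = make_record(
            years_in_union=None, used_contraception_past_5y=None, pregnant_in_past_5y=None,
            self_reported_infecund=None, menopause_hysterectomy_or_never_menstruated=None,
            months_since_last_period=None, postpartum_amenorrheic=None,
        )
        assert assess_fecundity(r) == ("excluded", "fecundity_indeterminate")

    def test_truth_table_matches_rule_list_oracle(self):
        """Exhaustive enumeration over the rule inputs against an
        independently coded rule list (lowest firing rule wins)."""
        rule_names = {1: "rule1_union5y", 2: "rule2_self_report",
                      3: "rule3_menopause", 4: "rule4_amenorrhea6m"}
        for years, used, preg5, self_rep, meno, months, ppa in itertools.product(
            (3.0, 5.0, 7.0), (True, False), (True, False), (True, False),
            (True, False), (0.0, 6.0, 7.0, 24.0), (True, False),
        ):
            r = make_record(
                years_in_union=years, used_contraception_past_5y=used,
                pregnant_in_past_5y=preg5, self_reported_infecund=self_rep,
                menopause_hysterectomy_or_never_menstruated=meno,
                months_since_last_period=months, postpartum_amenorrheic=ppa,
            )
            state, rule = oracle_fecundity(vars(r))
            expected = (state, rule_names.get(rule))
            assert assess_fecundity(r) == expected, vars(r)


class TestNeed:
    def test_any_user_has_met_need(self):
        assert assess_need(make_record(current_method="pill")) == "met_modern"
        assert assess_need(make_record(current_method="traditional")) == "met_traditional"

    def test_mistimed_pregnancy_is_unmet_need(self):
        r = make_record(currently_pregnant=True, pregnancy_wantedness="wanted_later")
        assert assess_need(r) == "unmet_need"

    def test_unsure_preference_is_unmet_need(self):
        r = make_record(fertility_preference="unsure")
        assert assess_need(r) == "unmet_need"

    def test_wanted_pregnancy_is_no_need(self):
        r = make_record(currently_pregnant=True, pregnancy_wantedness="wanted_then")
        assert assess_need(r) == "no_need"

    def test_missing_preference_policy(self):
        r = make_record(fertility_preference="not_applicable")
        assert assess_need(r) == "excluded"
        assert assess_need(r, missing_preference="no_need") == "no_need"


class TestDfpsFlags:
    def test_sterilization_user_in_numerator(self):
        st = dfps_flags(make_record(current_method="female_sterilization"))
        assert st.in_dfps_denominator and st.in_dfps_numerator
        assert st.method_class.action_class == "PERMANENT"

    def test_infecund_nonuser_not_in_denominator(self):
        st = dfps_flags(make_record(menopause_hysterectomy_or_never_menstruated=True))
        assert st.need == "no_need"
        assert not st.in_dfps_denominator

    def test_traditional_user_in_denominator_only(self):
        st = dfps_flags(make_record(current_method="traditional"))
        assert st.in_dfps_denominator and not st.in_dfps_numerator

    def test_preference_monotonicity(self):
        """Moving a non-user from wanting a child soon to wanting no
        more never removes her from the denominator."""
        for pregnant, ppa in ((False, False), (False, True)):
            base = make_record(
                currently_pregnant=pregnant, postpartum_amenorrheic=ppa,
                pregnancy_wantedness="wanted_later" if (pregnant or ppa) else "not_applicable",
                fertility_preference="wants_within_2y",
            )
            switched = make_record(**{**vars(base), "fertility_preference": "wants_no_more"})
            assert dfps_flags(switched).in_dfps_denominator >= dfps_flags(base).in_dfps_denominator

    def test_status_invariants_on_synthetic_sample(self, classified):
        ok = classified["excluded"].isna()
        num = classified["in_dfps_numerator"]
        den = classified["in_dfps_denominator"]
        assert (num <= den).all()
        assert (num[ok] == (classified.loc[ok, "need"] == "met_modern")).all()
        assert (
            den[ok]
            == classified.loc[ok, "need"].isin(["unmet_need", "met_traditional", "met_modern"])
        ).all()
        # action class is defined exactly for modern methods
        modern = classified["modernity"] == "modern"
        assert (classified.loc[modern, "action_class"] != "not_applicable").all()
        assert (classified.loc[~modern, "action_class"] == "not_applicable").all()


def test_classify_table_matches_per_record_path(sample_df):
    tbl = classify_table(sample_df)
    for i, row in enumerate(sample_df.sample(50, random_state=0).itertuples(index=False)):
        st = dfps_flags(row)
        got = tbl.loc[tbl["woman_id"] == row.woman_id].iloc[0]
        assert got["need"] == (st.need if st.need is not None else None) or (
            got["need"] is None and st.need is None
        )
        assert bool(got["in_dfps_numerator"]) == st.in_dfps_numerator
        assert bool(got["in_dfps_denominator"]) == st.in_dfps_denominator
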