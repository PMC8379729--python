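"""Result-artifact builders: method mix, panels, gaps, sterilization
profile, deterministic output."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fpequity.equity_report import (
    add_age_band,
    build_method_mix_table,
    build_region_table,
    build_sterilization_profile,
    build_stratified_panel,
    equity_gap,
    write_artifacts,
)
from fpequity.fp_status import attach_status
from fpequity.survey_estimation import EstimationError
from fpequity.synthetic_data import DesignParams, PopulationSpec, draw_survey, generate_census

from oracles import direct_weighted_mean


@pytest.fixture(scope="module")
def banded(classified):
    return add_age_band(classified)


class TestMethodMix:
    def test_class_rows_equal_sum_of_member_rows(self, banded):
        tbl = build_method_mix_table(banded, rare_threshold=0)
        for cls in ("SARC", "LARC", "PERMANENT"):
            class_share = tbl.loc[
                (tbl["row_type"] == "class") & (tbl["method_class"] == cls), "p_hat"
            ].iloc[0]
            member_sum = tbl.loc[
                (tbl["row_type"] == "method") & (tbl["method_class"] == cls), "p_hat"
            ].sum()
            assert class_share == pytest.approx(member_sum, abs=1e-9)

    def test_class_shares_sum_to_one(self, banded):
        tbl = build_method_mix_table(banded)
        total = tbl.loc[tbl["row_type"] == "class", "p_hat"].sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_column_layout(self, banded):
        tbl = build_method_mix_table(banded)
        assert list(tbl.columns) == [
            "row_type", "method_class", "method", "domain", "outcome", "p_hat", "se",
            "ci_low", "ci_high", "df", "n_unweighted", "n_weighted",
        ]

    def test_sterilization_only_population_has_permanent_share_one(self, banded):
        only = banded[banded["current_method"] == "female_sterilization"]
        tbl = build_method_mix_table(only)
        perm = tbl.loc[(tbl["row_type"] == "class") & (tbl["method_class"] == "PERMANENT"),
                       "p_hat"].iloc[0]
        assert perm == 1.0

    def test_rare_methods_are_counted_in_footnote(self, banded):
        full = build_method_mix_table(banded, rare_threshold=0)
        trimmed = build_method_mix_table(banded, rare_threshold=10)
        dropped = set(full.loc[full["row_type"] == "method", "method"]) - set(
            trimmed.loc[trimmed["row_type"] == "method", "method"]
        )
        modern = banded["in_dfps_numerator"]
        n_dropped = int((banded.loc[modern, "current_method"].isin(dropped)).sum())
        assert dropped and trimmed.attrs["n_rare_excluded"] == n_dropped

    def test_no_modern_users_raises(self, banded):
        none = banded[banded["current_method"] == "none"]
        with pytest.raises(EstimationError):
            build_method_mix_table(none)


class TestEquityGap:
    def _table(self, pairs):
        return pd.DataFrame(
            [{"level": k, "outcome": "dfps_modern", "p_hat": v} for k, v in pairs.items()]
        )

    def test_attitude_to_violence_worked_example(self):
        t = self._table({"low": 0.840, "high": 0.708})
        assert equity_gap(t, "low", "high") == pytest.approx(13.2, abs=1e-9)

    def test_social_independence_worked_example(self):
        t = self._table({"low": 0.870, "high": 0.645})
        assert equity_gap(t, "low", "high") == pytest.approx(22.5, abs=1e-9)

    def test_zero_and_sign(self):
        t = self._table({"a": 0.5, "b": 0.5, "c": 0.4})
        assert equity_gap(t, "a", "b") == 0.0
        assert equity_gap(t, "c", "a") == pytest.approx(-equity_gap(t, "a", "c"))

    def test_missing_level_raises(self):
        with pytest.raises(KeyError):
            equity_gap(self._table({"a": 0.5}), "a", "zzz")


class TestStratifiedPanel:
    def test_panel_has_all_outcomes_per_level(self, banded):
        panel = build_stratified_panel(banded, "wealth_quintile")
        assert set(panel["outcome"]) == {"dfps_modern", "share_SARC", "share_LARC",
                                         "share_PERMANENT"}
        counts = panel.groupby("outcome")["level"].count()
        assert (counts == 5).all()

    def test_class_shares_sum_to_one_within_level(self, banded):
        panel = build_stratified_panel(banded, "education_level")
        shares = panel[panel["outcome"].str.startswith("share_")]
        sums = shares.groupby("level")["p_hat"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)


class TestRegionTable:
    def test_one_row_block_per_region_and_annotations(self, banded):
        tbl = build_region_table(banded)
        regions = sorted(banded["region_code"].unique())
        dfps = tbl[tbl["outcome"] == "dfps_modern"]
        assert dfps["level"].tolist() == regions
        assert dfps.loc[dfps["is_min_dfps_region"], "p_hat"].iloc[0] == dfps["p_hat"].min()
        assert dfps.loc[dfps["is_max_dfps_region"], "p_hat"].iloc[0] == dfps["p_hat"].max()

    def test_single_region_input(self, banded):
        one = banded[banded["region_code"] == banded["region_code"].iloc[0]]
        tbl = build_region_table(one)
        assert (tbl[tbl["outcome"] == "dfps_modern"]).shape[0] == 1

    def test_two_region_truth_ordering(self):
        """With regionally tilted wealth, the region ranking of estimated
        DFPS matches the census truth ranking."""
        spec = PopulationSpec(n_strata=2, psus_per_stratum=60, psu_household_range=(20, 40),
                              wealth_tilt_by_region=(-1.2, 1.2))
        census, truth = generate_census(spec, 31)
        sample = draw_survey(census, DesignParams(n_psus_per_stratum=25), 32)
        tbl = build_region_table(attach_status(sample))
        dfps = tbl[tbl["outcome"] == "dfps_modern"].set_index("level")["p_hat"]
        t = truth.dfps_by["region_code"]
        assert (dfps["R01"] < dfps["R02"]) == (t["R01"] < t["R02"])


class TestSterilizationProfile:
    def test_band_shares_sum_to_one(self, banded):
        prof = build_sterilization_profile(banded)
        for panel in ("age_at_sterilization", "parity_at_sterilization"):
            s = prof.loc[prof["panel"] == panel, "p_hat"].sum()
            assert s == pytest.approx(1.0, abs=1e-9)

    def test_uniform_age_at_sterilization(self, banded):
        young = banded[banded["current_method"] == "female_sterilization"].copy()
        young["ster_age"] = 23.0
        prof = build_sterilization_profile(young)
        row = prof[(prof["panel"] == "age_at_sterilization") & (prof["level"] == "<25")]
        assert row["p_hat"].iloc[0] == 1.0

    def test_mean_compensation_matches_direct_oracle(self, banded):
        prof = build_sterilization_profile(banded)
        fs = (banded["current_method"] == "female_sterilization").to_numpy()
        comp = banded["ster_received_compensation"].fillna(False).to_numpy()
        for q in ("Q1", "Q3", "Q5"):
            mask = fs & comp & (banded["wealth_quintile"] == q).to_numpy()
            if not mask.any():
                continue
            want = direct_weighted_mean(
                banded["ster_compensation_amount"].to_numpy(dtype=float),
                banded["weight"].to_numpy(dtype=float), mask,
            )
            got = prof[(prof["panel"] == "mean_compensation_by_wealth")
                       & (prof["level"] == q)]["p_hat"].iloc[0]
            assert got == pytest.approx(want, rel=1e-12)

    def test_empty_domain_raises(self, banded):
        none = banded[banded["current_method"] == "none"]
        with pytest.raises(EstimationError):
            build_sterilization_profile(none)


def test_artifacts_are_byte_identical_on_rerun(banded, tmp_path):
    arts = {
        "table1_method_mix": build_method_mix_table(banded),
        "fig2_wealth_panel": build_stratified_panel(banded, "wealth_quintile"),
    }
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_artifacts(arts, d1)
    arts2 = {
        "table1_method_mix": build_method_mix_table(banded),
        "fig2_wealth_panel": build_stratified_panel(banded, "wealth_quintile"),
    }
    write_artifacts(arts2, d2)
    for name in arts:
        assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()
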