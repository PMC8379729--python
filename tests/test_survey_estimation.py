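"""Design-based estimator: point estimates, Taylor variances, CIs,
domain handling and invariances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fpequity.survey_estimation import (
    EstimationError,
    SurveyDesign,
    share_table,
    stratified_estimates,
    weighted_mean,
    weighted_proportion,
)

from oracles import bootstrap_se_ratio, direct_weighted_mean


def _toy_frame(strata=3, psus=2, per_psu=4, weights=None, y=None):
    rows = []
    k = 0
    for s in range(strata):
        for p in range(psus):
            for i in range(per_psu):
                rows.append({"stratum_id": f"S{s}", "psu_id": f"S{s}P{p}",
                             "weight": 1.0, "i": k})
                k += 1
    df = pd.DataFrame(rows)
    if weights is not None:
        df["weight"] = weights
    df["y"] = y if y is not None else 0
    return df


def test_equal_weights_reduce_to_arithmetic_mean():
    df = _toy_frame(strata=1, psus=2, per_psu=2, y=[1, 0, 1, 1])
    est = weighted_proportion(df, "y")
    assert est.p_hat == 0.75


def test_degenerate_proportion_has_degenerate_interval():
    df = _toy_frame(strata=1, psus=2, per_psu=3, y=[1] * 6)
    est = weighted_proportion(df, "y")
    assert (est.p_hat, est.se) == (1.0, 0.0)
    assert (est.ci_low, est.ci_high) == (1.0, 1.0)


def test_empty_domain_raises():
    df = _toy_frame(y=[0] * 24)
    with pytest.raises(EstimationError, match="empty domain"):
        weighted_proportion(df, "y", domain=np.zeros(24, dtype=bool))


# the printed 3-stratum, 12-PSU toy used for the variance cross-check
_TOY_WEIGHTS = [1.0, 1.5, 2.0, 1.2, 0.8] * 12
_TOY_Y = [
    1, 0, 1, 1, 0,   0, 0, 1, 0, 0,   1, 1, 1, 0, 1,   0, 1, 0, 0, 1,
    1, 1, 0, 1, 0,   0, 0, 0, 1, 0,   1, 0, 1, 1, 1,   0, 1, 1, 0, 0,
    1, 1, 1, 1, 0,   0, 0, 1, 0, 1,   1, 0, 0, 1, 0,   0, 1, 0, 1, 1,
]


def _printed_toy() -> pd.DataFrame:
    return _toy_frame(strata=3, psus=4, per_psu=5, weights=_TOY_WEIGHTS, y=_TOY_Y)


def test_taylor_se_close_to_bootstrap_oracle():
    """Linearized SE within 10% of a 10,000-replicate rescaled PSU
    bootstrap on the printed toy dataset."""
    df = _printed_toy()
    est = weighted_proportion(df, "y")
    boot = bootstrap_se_ratio(df, df["y"].to_numpy(dtype=float),
                              np.ones(len(df), dtype=bool), 10_000,
                              np.random.default_rng(2024))
    assert est.se == pytest.approx(boot, rel=0.10)


def test_weight_scale_invariance():
    df = _printed_toy()
    base = weighted_proportion(df, "y")
    scaled = df.copy()
    scaled["weight"] *= 137.5
    got = weighted_proportion(scaled, "y")
    assert got.p_hat == pytest.approx(base.p_hat, rel=1e-12)
    assert got.se == pytest.approx(base.se, rel=1e-12)
    assert got.ci_low == pytest.approx(base.ci_low, rel=1e-12)
    assert got.ci_high == pytest.approx(base.ci_high, rel=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    c=st.floats(min_value=1e-3, max_value=1e3),
    bits=st.integers(min_value=1, max_value=2**24 - 2),
)
def test_scale_invariance_over_outcome_patterns(c, bits):
    """Rescaling all weights by any constant leaves estimate, SE and CI
    unchanged for any 0/1 outcome pattern."""
    y = [(bits >> i) & 1 for i in range(24)]
    df = _toy_frame(strata=3, psus=2, per_psu=4, y=y)
    base = weighted_proportion(df, "y")
    scaled = df.assign(weight=df["weight"] * c)
    got = weighted_proportion(scaled, "y")
    assert got.p_hat == pytest.approx(base.p_hat, rel=1e-9, abs=1e-12)
    assert got.se == pytest.approx(base.se, rel=1e-9, abs=1e-12)
    assert got.ci_low == pytest.approx(base.ci_low, rel=1e-9, abs=1e-12)


def test_ci_contains_estimate_and_df_rule():
    df = _printed_toy()
    est = weighted_proportion(df, "y")
    assert est.ci_low <= est.p_hat <= est.ci_high
    assert 0.0 <= est.ci_low and est.ci_high <= 1.0
    assert est.df == 12 - 3


def test_domain_df_uses_domain_strata_only():
    df = _printed_toy()
    dom = (df["stratum_id"] == "S0").to_numpy()
    est = weighted_proportion(df, "y", domain=dom)
    assert est.df == 4 - 1
    assert est.n_unweighted == 20


def test_domain_estimation_keeps_out_of_domain_psus():
    """Zero-weighting, not subsetting: the domain SE reflects the
    clustering of domain members across all PSUs."""
    df = _printed_toy()
    rng = np.random.default_rng(5)
    dom = rng.random(len(df)) < 0.6
    est = weighted_proportion(df, "y", domain=dom)
    boot = bootstrap_se_ratio(df, df["y"].to_numpy(dtype=float), dom, 10_000,
                              np.random.default_rng(77))
    assert est.se == pytest.approx(boot, rel=0.15)


def test_lonely_psu_collapse_and_error_policies():
    df = _toy_frame(strata=1, psus=1, per_psu=6, y=[1, 0, 1, 0, 1, 1])
    extra = _toy_frame(strata=1, psus=2, per_psu=3, y=[1, 0, 1, 0, 0, 1])
    extra["stratum_id"] = "T"
    extra["psu_id"] = "T" + extra["psu_id"]
    both = pd.concat([df, extra], ignore_index=True)
    est = weighted_proportion(both, "y")  # collapse succeeds
    assert np.isfinite(est.se)
    with pytest.raises(EstimationError, match="single-PSU"):
        weighted_proportion(both, "y", design=SurveyDesign(lonely_psu="error"))


def test_share_table_partition_sums_to_one(classified):
    dom = classified["in_dfps_numerator"].to_numpy()
    rows = share_table(classified, "action_class", dom)
    total = sum(r.p_hat for r in rows)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_share_table_single_category():
    df = _toy_frame(strata=1, psus=2, per_psu=3)
    df["cls"] = "A"
    rows = share_table(df, "cls")
    assert len(rows) == 1 and rows[0].p_hat == 1.0


def test_stratified_symmetry_between_identical_halves():
    df = _printed_toy()
    mirror = df.copy()
    mirror["stratum_id"] = "M" + mirror["stratum_id"]
    mirror["psu_id"] = "M" + mirror["psu_id"]
    both = pd.concat([df.assign(half="a"), mirror.assign(half="b")], ignore_index=True)
    out = stratified_estimates(both, "y", "half")
    a, b = out.iloc[0], out.iloc[1]
    assert a["p_hat"] == pytest.approx(b["p_hat"], rel=1e-12)
    assert a["se"] == pytest.approx(b["se"], rel=1e-12)


def test_stratified_levels_aggregate_to_pooled(classified):
    """Law of total probability: the weight-share-weighted average of
    level estimates equals the pooled estimate."""
    dom = classified["in_dfps_denominator"].to_numpy()
    pooled = weighted_proportion(classified, "in_dfps_numerator", dom)
    out = stratified_estimates(classified, "in_dfps_numerator", "wealth_quintile", dom)
    shares = out["n_weighted"] / out["n_weighted"].sum()
    combined = float((out["p_hat"] * shares).sum())
    assert combined == pytest.approx(pooled.p_hat, abs=1e-9)


def test_stratified_unknown_level_raises(classified):
    with pytest.raises(EstimationError, match="no level"):
        stratified_estimates(
            classified, "in_dfps_numerator", "wealth_quintile",
            classified["in_dfps_denominator"].to_numpy(), levels=["Q9"],
        )


def test_weighted_mean_matches_direct_oracle(classified):
    fs = (classified["current_method"] == "female_sterilization").to_numpy()
    est = weighted_mean(classified, "ster_compensation_amount",
                        fs & classified["ster_received_compensation"].fillna(False).to_numpy())
    want = direct_weighted_mean(
        classified["ster_compensation_amount"].to_numpy(dtype=float),
        classified["weight"].to_numpy(dtype=float),
        fs & classified["ster_received_compensation"].fillna(False).to_numpy(),
    )
    assert est.p_hat == pytest.approx(want, rel=1e-12)
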