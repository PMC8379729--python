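"""Result-table builders: method mix, stratified panels, per-region
tables, equity gaps and the sterilization profile.

Every builder returns a tidy :class:`pandas.DataFrame` of survey-weighted
estimates (point, SE, logit-Wald CI, df, counts) ready to be written as
a delimited file; :func:`write_artifacts` serializes a set of them with
fixed ordering and float formatting so that re-running on identical
input is byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .fp_status import SARC_METHODS, LARC_METHODS, PERMANENT_METHODS
from .survey_estimation import (
    EstimationError,
    SurveyDesign,
    rows_to_frame,
    stratified_estimates,
    weighted_mean,
    weighted_proportion,
)

__all__ = [
    "build_method_mix_table",
    "build_stratified_panel",
    "build_region_table",
    "build_sterilization_profile",
    "equity_gap",
    "add_age_band",
    "write_artifacts",
    "STRATIFIER_PANELS",
]

AGE_BAND_EDGES = (15, 20, 25, 30, 35, 40, 45, 50)
AGE_BAND_LABELS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")

#: the standard stratified panels (figure analogues): stratifier column
#: -> output artifact name
STRATIFIER_PANELS = {
    "age_band": "fig1_age_panel",
    "wealth_quintile": "fig2_wealth_panel",
    "education_level": "fig3_education_panel",
    "swper_cat_attitude_to_violence": "fig5_swper_attitude_to_violence_panel",
    "swper_cat_social_independence": "fig5_swper_social_independence_panel",
    "swper_cat_decision_making": "fig5_swper_decision_making_panel",
}

_CLASS_MEMBERS = {
    "SARC": tuple(sorted(SARC_METHODS)),
    "LARC": tuple(sorted(LARC_METHODS)),
    "PERMANENT": tuple(sorted(PERMANENT_METHODS)),
}


def add_age_band(df: pd.DataFrame, grouping: str = "5year") -> pd.DataFrame:
    """Add an ``age_band`` column (5-year bands, or single years)."""
    out = df.copy()
    if grouping == "single":
        out["age_band"] = out["age_years"].astype(int).astype(str)
    elif grouping == "5year":
        out["age_band"] = pd.cut(
            out["age_years"],
            bins=list(AGE_BAND_EDGES),
            labels=list(AGE_BAND_LABELS),
            right=False,
        ).astype(str)
    else:
        raise ValueError("grouping must be '5year' or 'single'")
    return out


def build_method_mix_table(
    classified: pd.DataFrame,
    design: SurveyDesign | None = None,
    rare_threshold: int = 10,
) -> pd.DataFrame:
    """Method-mix table among modern users: class rows plus
    specific-method rows nested under their class.

    Specific methods used by fewer than ``rare_threshold`` women
    (unweighted) are left out of the table and counted in the
    ``n_rare_excluded`` attribute of the result, mirroring the usual
    presentation of negligible categories; class shares always include
    them, so class rows equal the sum of their member rows only when no
    rare methods are present.
    """
    design = design or SurveyDesign()
    domain = classified["in_dfps_numerator"].to_numpy()
    if not domain.any():
        raise EstimationError("no modern users in the data")
    method = classified["current_method"]
    rows = []
    labels = []
    n_rare = 0
    for cls, members in _CLASS_MEMBERS.items():
        rows.append(
            weighted_proportion(
                classified,
                (classified["action_class"] == cls).to_numpy(),
                domain,
                design,
                domain_label="modern_users",
                outcome_label=cls,
            )
        )
        labels.append(("class", cls, ""))
        for m in members:
            n_users = int(((method == m) & domain).sum())
            if n_users == 0:
                continue
            if n_users < rare_threshold:
                n_rare += n_users
                continue
            rows.append(
                weighted_proportion(
                    classified,
                    (method == m).to_numpy(),
                    domain,
                    design,
                    domain_label="modern_users",
                    outcome_label=m,
                )
            )
            labels.append(("method", cls, m))
    out = rows_to_frame(rows)
    out.insert(0, "row_type", [l[0] for l in labels])
    out.insert(1, "method_class", [l[1] for l in labels])
    out.insert(2, "method", [l[2] for l in labels])
    out.attrs["n_rare_excluded"] = n_rare
    return out


def build_stratified_panel(
    classified: pd.DataFrame,
    stratifier: str,
    design: SurveyDesign | None = None,
    levels: list[str] | None = None,
) -> pd.DataFrame:
    """DFPS plus the three class shares for every level of a stratifier.

    One block of rows per outcome: ``dfps_modern`` is estimated among
    women in need; the class shares among modern users.  Levels with no
    domain members are flagged with NaN estimates rather than dropped.
    """
    design = design or SurveyDesign()
    parts = [
        stratified_estimates(
            classified,
            "in_dfps_numerator",
            stratifier,
            classified["in_dfps_denominator"].to_numpy(),
            design,
            levels=levels,
            outcome_label="dfps_modern",
        )
    ]
    modern = classified["in_dfps_numerator"].to_numpy()
    for cls in ("SARC", "LARC", "PERMANENT"):
        parts.append(
            stratified_estimates(
                classified,
                (classified["action_class"] == cls).to_numpy(),
                stratifier,
                modern,
                design,
                levels=levels,
                outcome_label=f"share_{cls}",
            )
        )
    return pd.concat(parts, ignore_index=True)


def build_region_table(
    classified: pd.DataFrame, design: SurveyDesign | None = None
) -> pd.DataFrame:
    """Per-region DFPS and class shares, with min/max DFPS regions
    annotated (the geographic-spread summary)."""
    panel = build_stratified_panel(classified, "region_code", design)
    dfps = panel[panel["outcome"] == "dfps_modern"].set_index("level")["p_hat"]
    lo, hi = dfps.idxmin(), dfps.idxmax()
    panel["is_min_dfps_region"] = panel["level"].eq(lo)
    panel["is_max_dfps_region"] = panel["level"].eq(hi)
    return panel


def equity_gap(
    estimates: pd.DataFrame, level_a: str, level_b: str, outcome: str | None = None
) -> float:
    """Percentage-point difference ``100 * (p_a - p_b)`` between two
    levels of a stratified estimate table (signed)."""
    t = estimates
    if outcome is not None:
        t = t[t["outcome"] == outcome]
    sub = t.set_index("level")["p_hat"]
    for lv in (level_a, level_b):
        if lv not in sub.index:
            raise KeyError(f"level {lv!r} not present in the estimate table")
    return float(100.0 * (sub[level_a] - sub[level_b]))


_AGE_AT_STER_BANDS = ("<25", "25-29", "30-34", ">=35")
_PARITY_BANDS = ("0-1", "2", "3", "4+")


def _ster_bands(classified: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sa = classified["ster_age"].to_numpy(dtype=float)
    sp = classified["ster_parity"].to_numpy(dtype=float)
    age_band = np.select([sa < 25, sa < 30, sa < 35], _AGE_AT_STER_BANDS[:3], _AGE_AT_STER_BANDS[3])
    parity_band = np.select([sp <= 1, sp == 2, sp == 3], _PARITY_BANDS[:3], _PARITY_BANDS[3])
    return age_band, parity_band


def build_sterilization_profile(
    classified: pd.DataFrame, design: SurveyDesign | None = None
) -> pd.DataFrame:
    """Survey-weighted profile of sterilized women (female
    sterilization): age and parity at sterilization band shares, the
    share not told the procedure was permanent, regret (overall and by
    parity at sterilization), monetary compensation (overall and by
    wealth quintile) and mean compensation amount (rupees) by quintile.
    """
    design = design or SurveyDesign()
    fs = (classified["current_method"] == "female_sterilization").to_numpy()
    if not fs.any():
        raise EstimationError("no sterilized women in the data")
    age_band, parity_band = _ster_bands(classified)
    not_told = ~classified["ster_told_no_more"].astype("boolean").fillna(True).to_numpy()
    regret = classified["ster_regrets"].astype("boolean").fillna(False).to_numpy()
    comp = classified["ster_received_compensation"].astype("boolean").fillna(False).to_numpy()

    rows = []
    tags = []
    for band in _AGE_AT_STER_BANDS:
        rows.append(weighted_proportion(classified, age_band == band, fs, design,
                                        "sterilized", band))
        tags.append(("age_at_sterilization", band))
    for band in _PARITY_BANDS:
        rows.append(weighted_proportion(classified, parity_band == band, fs, design,
                                        "sterilized", band))
        tags.append(("parity_at_sterilization", band))
    rows.append(weighted_proportion(classified, not_told, fs, design, "sterilized", "not_told"))
    tags.append(("not_told_no_more_children", "all"))
    rows.append(weighted_proportion(classified, regret, fs, design, "sterilized", "regret"))
    tags.append(("regret", "all"))
    for band in _PARITY_BANDS:
        dom = fs & (parity_band == band)
        rows.append(weighted_proportion(classified, regret, dom, design,
                                        f"sterilized_parity_{band}", "regret"))
        tags.append(("regret_by_parity", band))
    rows.append(weighted_proportion(classified, comp, fs, design, "sterilized", "compensated"))
    tags.append(("received_compensation", "all"))
    quintiles = ("Q1", "Q2", "Q3", "Q4", "Q5")
    wq = classified["wealth_quintile"]
    for q in quintiles:
        dom = fs & (wq == q).to_numpy()
        rows.append(weighted_proportion(classified, comp, dom, design, f"sterilized_{q}",
                                        "compensated"))
        tags.append(("received_compensation_by_wealth", q))
    for q in quintiles:
        dom = fs & (wq == q).to_numpy() & comp
        rows.append(weighted_mean(classified, "ster_compensation_amount", dom, design,
                                  f"sterilized_{q}", "mean_compensation_rupees"))
        tags.append(("mean_compensation_by_wealth", q))

    out = rows_to_frame(rows)
    out.insert(0, "panel", [t[0] for t in tags])
    out.insert(1, "level", [t[1] for t in tags])
    return out


def write_artifacts(artifacts: Mapping[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each artifact as CSV with deterministic formatting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(artifacts):
        path = outdir / f"{name}.csv"
        artifacts[name].to_csv(path, index=False, float_format="%.8g")
        written.append(path)
    return written
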