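"""Independent reference implementations used only by the test suite.

These are deliberately written as flat rule lists / direct summations,
structured differently from the package code, so they can serve as
independent cross-checks of the classification and estimation paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODERN_ORACLE = {
    "pill", "injectable", "condom", "diaphragm", "spermicide", "emergency",
    "iud", "female_sterilization", "male_sterilization", "other_modern",
}


def oracle_fecundity(rec: dict) -> tuple[str, int]:
    """Rule-list fecundity oracle; returns (state, firing rule or 0)."""
    if rec["currently_pregnant"]:
        return "fecund", 0
    if (
        rec["years_in_union"] >= 5
        and rec["used_contraception_past_5y"] is False
        and rec["pregnant_in_past_5y"] is False
    ):
        return "infecund", 1
    if rec["self_reported_infecund"] is True:
        return "infecund", 2
    if rec["menopause_hysterectomy_or_never_menstruated"] is True:
        return "infecund", 3
    months = rec["months_since_last_period"]
    if months is not None and months > 6 and rec["postpartum_amenorrheic"] is False:
        return "infecund", 4
    return "fecund", 0


def oracle_need(rec: dict) -> str:
    """Decision-table oracle for the need state (fully observed input).

    Returns one of no_need / unmet_need / met_traditional / met_modern /
    excluded.
    """
    method = rec["current_method"]
    if method in MODERN_ORACLE:
        return "met_modern"
    if method == "traditional":
        return "met_traditional"
    # non-users from here on
    if rec["currently_pregnant"] or rec["postpartum_amenorrheic"]:
        table = {
            "wanted_then": "no_need",
            "wanted_later": "unmet_need",
            "wanted_not_at_all": "unmet_need",
        }
        return table.get(rec["pregnancy_wantedness"], "excluded")
    state, _rule = oracle_fecundity(rec)
    if state == "infecund":
        return "no_need"
    table = {
        "wants_within_2y": "no_need",
        "wants_after_2y": "unmet_need",
        "wants_no_more": "unmet_need",
        "unsure": "unmet_need",
    }
    return table.get(rec["fertility_preference"], "excluded")


def oracle_domain_scores(items: np.ndarray, weights: np.ndarray, intercepts: np.ndarray,
                         centers: np.ndarray, scales: np.ndarray) -> list[float]:
    """Plain-loop dot product oracle for the SWPER linear scores
    (complete item vectors only)."""
    out = []
    for d in range(3):
        raw = intercepts[d]
        for k in range(len(items)):
            raw += weights[d][k] * items[k]
        out.append((raw - centers[d]) / scales[d])
    return out


def bootstrap_se_ratio(
    df: pd.DataFrame,
    y: np.ndarray,
    domain: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    stratum_col: str = "stratum_id",
    psu_col: str = "psu_id",
    weight_col: str = "weight",
) -> float:
    """Rao-Wu rescaled PSU bootstrap SE for the weighted proportion.

    Within each stratum of n_h PSUs, m_h = n_h - 1 PSUs are resampled
    with replacement and PSU weights rescaled by (n_h / m_h) x the
    resampling count, which makes the bootstrap variance match the
    with-replacement design variance for linear statistics.
    """
    w = df[weight_col].to_numpy(dtype=float)
    num_i = w * domain * y
    den_i = w * domain
    tots = (
        pd.DataFrame(
            {
                "stratum": df[stratum_col].to_numpy(),
                "psu": df[psu_col].to_numpy(),
                "num": num_i,
                "den": den_i,
            }
        )
        .groupby(["stratum", "psu"], sort=True)
        .sum()
    )
    num_b = np.zeros(n_boot)
    den_b = np.zeros(n_boot)
    for _, g in tots.groupby(level="stratum", sort=True):
        n_h = len(g)
        counts = rng.multinomial(n_h - 1, np.full(n_h, 1.0 / n_h), size=n_boot)
        factor = counts * (n_h / (n_h - 1))
        num_b += factor @ g["num"].to_numpy()
        den_b += factor @ g["den"].to_numpy()
    p_b = num_b / den_b
    return float(p_b.std(ddof=1))


def direct_weighted_mean(values: np.ndarray, weights: np.ndarray, mask: np.ndarray) -> float:
    v = values[mask]
    w = weights[mask]
    keep = ~np.isnan(v)
    return float((v[keep] * w[keep]).sum() / w[keep].sum())
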