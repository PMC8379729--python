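"""Family-planning status classification.

Implements the demand-for-family-planning-satisfied (DFPS) indicator for
partnered women aged 15-49: the proportion of women in need of
contraception who are using a *modern* method.  The classification has
three layers:

1. **Method class** — every contraceptive method is mapped to a
   modernity (modern / traditional / none) and, for modern methods, an
   action class: SARC (short-acting reversible: pill, injectable,
   condom, diaphragm, spermicide, emergency contraception), LARC
   (long-acting reversible: IUD only) or PERMANENT (female and male
   sterilization).

2. **Fecundity** — a non-user is infecund if any of four rules fires
   (lowest-numbered firing rule is reported):
   (1) in union five or more years, used no contraception and had no
   pregnancy in that period; (2) self-reports that she cannot get
   pregnant; (3) reports menopause, hysterectomy or never menstruated;
   (4) last menstrual period more than six months ago while not
   postpartum amenorrheic.  A currently pregnant woman is always fecund.

3. **Need** — decision order: a current user of any method has her need
   met (modern or traditional); otherwise a pregnant or postpartum
   amenorrheic woman is in unmet need iff the (last) pregnancy was
   mistimed or unwanted; otherwise an infecund woman has no need, and a
   fecund woman is in unmet need iff she wants no child within the next
   two years or is unsure.

Current users bypass the fecundity rules and always sit in the DFPS
denominator — rule (1) explicitly conditions on non-use, and sterilized
or amenorrheic users must count as met need for the indicator to be
well defined.  Traditional-method users are in the denominator but not
the numerator.  Records whose need cannot be determined are excluded
with a reason code, never silently classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .io_model import METHODS

__all__ = [
    "MethodClass",
    "FPStatus",
    "classify_method",
    "assess_fecundity",
    "assess_need",
    "dfps_flags",
    "classify_table",
    "SARC_METHODS",
    "LARC_METHODS",
    "PERMANENT_METHODS",
]

SARC_METHODS = frozenset({"pill", "injectable", "condom", "diaphragm", "spermicide", "emergency"})
LARC_METHODS = frozenset({"iud"})
PERMANENT_METHODS = frozenset({"female_sterilization", "male_sterilization"})
MODERN_METHODS = SARC_METHODS | LARC_METHODS | PERMANENT_METHODS | {"other_modern"}

UNMET_PREFERENCES = ("wants_after_2y", "wants_no_more", "unsure")
MISTIMED_OR_UNWANTED = ("wanted_later", "wanted_not_at_all")

_RULE_NAMES = ("rule1_union5y", "rule2_self_report", "rule3_menopause", "rule4_amenorrhea6m")


@dataclass(frozen=True)
class MethodClass:
    modernity: str  # modern | traditional | none
    action_class: str  # SARC | LARC | PERMANENT | not_applicable


@dataclass(frozen=True)
class FPStatus:
    """Complete derived classification for one woman."""

    fecundity: str | None  # fecund | infecund | None when excluded
    infecundity_reason: str | None
    need: str | None  # no_need | unmet_need | met_traditional | met_modern
    method_class: MethodClass
    in_dfps_denominator: bool
    in_dfps_numerator: bool
    excluded: str | None = None


def classify_method(current_method: str, other_modern_class: str = "SARC") -> MethodClass:
    """Map a method code to (modernity, action class).

    ``other_modern_class`` decides where the residual "other modern"
    category (implants, patches) falls; implants are long-acting and
    patches short-acting, and the category carries no sub-code, so the
    assignment is configurable.
    """
    if current_method not in METHODS:
        raise ValueError(f"unknown contraceptive method code: {current_method!r}")
    if current_method == "none":
        return MethodClass("none", "not_applicable")
    if current_method == "traditional":
        return MethodClass("traditional", "not_applicable")
    if current_method == "other_modern":
        if other_modern_class not in ("SARC", "LARC"):
            raise ValueError("other_modern_class must be 'SARC' or 'LARC'")
        return MethodClass("modern", other_modern_class)
    if current_method in SARC_METHODS:
        return MethodClass("modern", "SARC")
    if current_method in LARC_METHODS:
        return MethodClass("modern", "LARC")
    return MethodClass("modern", "PERMANENT")


def _missing(v: Any) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return v is pd.NA


def assess_fecundity(record: Any) -> tuple[str, str | None]:
    """Evaluate the four infecundity rules for a non-using woman.

    Returns ``("fecund", None)``, ``("infecund", reason)`` with the
    lowest-numbered firing rule, or ``("excluded",
    "fecundity_indeterminate")`` when every rule's inputs are missing.
    Rules with partially missing inputs evaluate to unknown and simply
    cannot fire.
    """
    if not _missing(record.currently_pregnant) and record.currently_pregnant:
        return "fecund", None

    rules: list[bool | None] = []

    yiu = record.years_in_union
    used = record.used_contraception_past_5y
    preg5 = record.pregnant_in_past_5y
    if _missing(yiu) or _missing(used) or _missing(preg5):
        rules.append(None)
    else:
        rules.append(yiu >= 5 and not used and not preg5)

    rules.append(None if _missing(record.self_reported_infecund) else bool(record.self_reported_infecund))
    rules.append(
        None
        if _missing(record.menopause_hysterectomy_or_never_menstruated)
        else bool(record.menopause_hysterectomy_or_never_menstruated)
    )

    months = record.months_since_last_period
    ppa = record.postpartum_amenorrheic
    if _missing(months) or _missing(ppa):
        rules.append(None)
    else:
        rules.append(months > 6 and not ppa)

    for name, fired in zip(_RULE_NAMES, rules):
        if fired:
            return "infecund", name
    if all(r is None for r in rules):
        return "excluded", "fecundity_indeterminate"
    return "fecund", None


def _compose(
    record: Any, other_modern_class: str = "SARC", missing_preference: str = "exclude"
) -> FPStatus:
    method = record.current_method
    if _missing(method):
        return FPStatus(None, None, None, MethodClass("none", "not_applicable"), False, False,
                        excluded="method_missing")
    mc = classify_method(method, other_modern_class)

    # (a) current users: need met by definition of the indicator
    if method != "none":
        need = "met_modern" if mc.modernity == "modern" else "met_traditional"
        return FPStatus("fecund", None, need, mc, True, need == "met_modern")

    # (b) pregnant or postpartum amenorrheic: wantedness of the pregnancy
    pregnant = (not _missing(record.currently_pregnant)) and bool(record.currently_pregnant)
    ppa = (not _missing(record.postpartum_amenorrheic)) and bool(record.postpartum_amenorrheic)
    if pregnant or ppa:
        fec, reason = ("fecund", None) if pregnant else assess_fecundity(record)
        w = record.pregnancy_wantedness
        if _missing(w) or w == "not_applicable":
            return FPStatus(fec if fec != "excluded" else None,
                            reason if fec == "infecund" else None,
                            None, mc, False, False, excluded="wantedness_missing")
        need = "unmet_need" if w in MISTIMED_OR_UNWANTED else "no_need"
        return FPStatus(fec if fec != "excluded" else "fecund",
                        reason if fec == "infecund" else None,
                        need, mc, need == "unmet_need", False)

    # (c) non-user, non-pregnant
    fec, reason = assess_fecundity(record)
    if fec == "excluded":
        return FPStatus(None, None, None, mc, False, False, excluded=reason)
    if fec == "infecund":
        return FPStatus("infecund", reason, "no_need", mc, False, False)
    pref = record.fertility_preference
    if pref in UNMET_PREFERENCES:
        return FPStatus("fecund", None, "unmet_need", mc, True, False)
    if pref == "wants_within_2y":
        return FPStatus("fecund", None, "no_need", mc, False, False)
    if missing_preference == "no_need":
        return FPStatus("fecund", None, "no_need", mc, False, False)
    return FPStatus("fecund", None, None, mc, False, False, excluded="preference_missing")


def assess_need(
    record: Any, other_modern_class: str = "SARC", missing_preference: str = "exclude"
) -> str:
    """Need state for one woman: no_need / unmet_need / met_traditional /
    met_modern, or ``"excluded"`` when indeterminate."""
    st = _compose(record, other_modern_class, missing_preference)
    return st.need if st.excluded is None else "excluded"


def dfps_flags(
    record: Any, other_modern_class: str = "SARC", missing_preference: str = "exclude"
) -> FPStatus:
    """Full FPStatus: composes method class, fecundity and need into
    DFPS numerator/denominator membership."""
    return _compose(record, other_modern_class, missing_preference)


#: columns emitted by :func:`classify_table`
STATUS_COLUMNS = (
    "woman_id",
    "fecundity",
    "infecundity_reason",
    "need",
    "modernity",
    "action_class",
    "in_dfps_denominator",
    "in_dfps_numerator",
    "excluded",
)


def classify_table(
    df: pd.DataFrame, other_modern_class: str = "SARC", missing_preference: str = "exclude"
) -> pd.DataFrame:
    """Apply :func:`dfps_flags` to every row of a canonical table.

    Returns one row per input woman, keyed by ``woman_id``, in input
    order.
    """
    out = {c: [] for c in STATUS_COLUMNS}
    for row in df.itertuples(index=False):
        st = _compose(row, other_modern_class, missing_preference)
        out["woman_id"].append(row.woman_id)
        out["fecundity"].append(st.fecundity)
        out["infecundity_reason"].append(st.infecundity_reason)
        out["need"].append(st.need)
        out["modernity"].append(st.method_class.modernity)
        out["action_class"].append(st.method_class.action_class)
        out["in_dfps_denominator"].append(st.in_dfps_denominator)
        out["in_dfps_numerator"].append(st.in_dfps_numerator)
        out["excluded"].append(st.excluded)
    res = pd.DataFrame(out)
    res["in_dfps_denominator"] = res["in_dfps_denominator"].astype(bool)
    res["in_dfps_numerator"] = res["in_dfps_numerator"].astype(bool)
    return res


def attach_status(df: pd.DataFrame, **kwargs: Any) -> pd.DataFrame:
    """Convenience: canonical table with FPStatus columns appended."""
    status = classify_table(df, **kwargs).drop(columns=["woman_id"])
    return pd.concat([df.reset_index(drop=True), status], axis=1)
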