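"""Schema and I/O for woman-level family-planning survey microdata.

The whole package operates on one flat rectangular table: one row per
woman aged 15-49 who is currently married or in union, carrying survey
design variables (stratum, PSU, household, sampling weight),
demographics, reproductive state, current contraceptive method,
sterilization details and the 14 items of the SWPER empowerment index.

This module owns that schema: canonical column names and category
labels, a column dictionary that maps external files (e.g. DHS-style
recodes) onto the schema, record-level validation, and a QC report that
accounts for every excluded row so that

    retained + sum(exclusions) == rows read.

The on-disk contract is a delimited text file (CSV by default) with a
header row; booleans are written as 0/1 and missing values as empty
fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_COLUMNS",
    "CATEGORY_LEVELS",
    "ColumnDictionary",
    "QCReport",
    "SchemaError",
    "CategoryError",
    "SterilizationDetail",
    "WomanRecord",
    "read_women_table",
    "write_women_table",
    "records_from_frame",
    "frame_from_records",
    "validate_record",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the file cannot be interpreted."""


class CategoryError(ValueError):
    """A cell holds a category code that no recode table can map."""


# ---------------------------------------------------------------------------
# canonical schema
# ---------------------------------------------------------------------------

METHODS = (
    "none",
    "pill",
    "injectable",
    "condom",
    "diaphragm",
    "spermicide",
    "emergency",
    "iud",
    "female_sterilization",
    "male_sterilization",
    "traditional",
    "other_modern",
)
STERILIZATION_METHODS = ("female_sterilization", "male_sterilization")

EDUCATION_LEVELS = ("none", "primary", "secondary_or_higher")
WEALTH_QUINTILES = ("Q1", "Q2", "Q3", "Q4", "Q5")
WANTEDNESS_LEVELS = ("wanted_then", "wanted_later", "wanted_not_at_all", "not_applicable")
PREFERENCE_LEVELS = ("wants_within_2y", "wants_after_2y", "wants_no_more", "unsure", "not_applicable")

VIOLENCE_ANSWERS = ("justified", "dont_know", "not_justified")
READING_ANSWERS = ("not_at_all", "less_than_weekly", "weekly")
DECISION_ANSWERS = ("husband_or_other", "joint", "respondent_alone")

#: The 14 SWPER items in canonical order: 5 attitude-to-violence items,
#: 6 social-independence items, 3 decision-making items.
SWPER_ITEM_COLUMNS = (
    "att_beat_goes_out",
    "att_beat_neglects_children",
    "att_beat_argues",
    "att_beat_refuses_sex",
    "att_beat_burns_food",
    "freq_reading",
    "education_years",
    "age_first_cohabitation",
    "age_first_birth",
    "age_difference",
    "education_difference",
    "decide_health",
    "decide_purchases",
    "decide_visits",
)

DESIGN_COLUMNS = ("stratum_id", "psu_id", "household_id", "weight")

STERILIZATION_COLUMNS = (
    "ster_age",
    "ster_parity",
    "ster_told_no_more",
    "ster_received_compensation",
    "ster_compensation_amount",
    "ster_regrets",
)

MANDATORY_COLUMNS = (
    "woman_id",
    *DESIGN_COLUMNS,
    "age_years",
    "in_union",
    "education_level",
    "wealth_quintile",
    "region_code",
    "currently_pregnant",
    "pregnancy_wantedness",
    "fertility_preference",
    "current_method",
    "self_reported_infecund",
    "menopause_hysterectomy_or_never_menstruated",
    "months_since_last_period",
    "postpartum_amenorrheic",
    "years_in_union",
    "used_contraception_past_5y",
    "pregnant_in_past_5y",
)

CANONICAL_COLUMNS = (*MANDATORY_COLUMNS, *STERILIZATION_COLUMNS, *SWPER_ITEM_COLUMNS)

#: Allowed levels for each categorical column (missing is always allowed
#: in the optional columns).
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "education_level": EDUCATION_LEVELS,
    "wealth_quintile": WEALTH_QUINTILES,
    "pregnancy_wantedness": WANTEDNESS_LEVELS,
    "fertility_preference": PREFERENCE_LEVELS,
    "current_method": METHODS,
    "freq_reading": READING_ANSWERS,
    **{c: VIOLENCE_ANSWERS for c in SWPER_ITEM_COLUMNS[:5]},
    **{c: DECISION_ANSWERS for c in SWPER_ITEM_COLUMNS[11:14]},
}

#: Mandatory boolean flags (missing not allowed after reading).
BOOL_COLUMNS = (
    "in_union",
    "currently_pregnant",
    "self_reported_infecund",
    "menopause_hysterectomy_or_never_menstruated",
    "postpartum_amenorrheic",
    "used_contraception_past_5y",
    "pregnant_in_past_5y",
)
#: Optional boolean flags (sterilization sub-record).
OPTIONAL_BOOL_COLUMNS = ("ster_told_no_more", "ster_received_compensation", "ster_regrets")

_NUMERIC_COLUMNS = (
    "weight",
    "age_years",
    "months_since_last_period",
    "years_in_union",
    "ster_age",
    "ster_parity",
    "ster_compensation_amount",
    "education_years",
    "age_first_cohabitation",
    "age_first_birth",
    "age_difference",
    "education_difference",
)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SterilizationDetail:
    """Details of a sterilization, attached to sterilized women only."""

    age_at_sterilization: float | None = None
    parity_at_sterilization: float | None = None
    told_means_no_more_children: bool | None = None
    received_compensation: bool | None = None
    compensation_amount: float | None = None
    regrets: bool | None = None


@dataclass(frozen=True)
class WomanRecord:
    """One respondent: a validated row of the canonical table.

    ``swper_items`` maps the 14 canonical item columns to their raw
    (un-recoded) values; categorical items hold label strings, numeric
    items hold numbers, missing items hold ``None``.
    """

    woman_id: str
    stratum_id: str
    psu_id: str
    household_id: str
    weight: float
    age_years: int
    in_union: bool
    education_level: str
    wealth_quintile: str
    region_code: str
    currently_pregnant: bool
    pregnancy_wantedness: str
    fertility_preference: str
    current_method: str
    self_reported_infecund: bool
    menopause_hysterectomy_or_never_menstruated: bool
    months_since_last_period: float | None
    postpartum_amenorrheic: bool
    years_in_union: float
    used_contraception_past_5y: bool
    pregnant_in_past_5y: bool
    sterilization: SterilizationDetail | None = None
    swper_items: Mapping[str, Any] = field(default_factory=dict)


def validate_record(record: WomanRecord) -> list[str]:
    """Check type invariants; return violation codes (empty == valid).

    Pure function: violations annotate, they never raise.
    """
    codes: list[str] = []
    if not (record.weight is not None and record.weight > 0):
        codes.append("nonpositive_weight")
    if not (15 <= record.age_years <= 49):
        codes.append("age_out_of_range")
    if not record.in_union:
        codes.append("not_in_union")
    if record.current_method not in METHODS:
        codes.append("unknown_method")
    if record.years_in_union is not None and record.years_in_union < 0:
        codes.append("negative_union_duration")
    if record.months_since_last_period is not None and not np.isnan(
        record.months_since_last_period
    ):
        if record.months_since_last_period < 0:
            codes.append("negative_months_since_period")
    sterilized = record.current_method in STERILIZATION_METHODS
    if sterilized and record.sterilization is None:
        codes.append("sterilization_detail_missing")
    if not sterilized and record.sterilization is not None:
        codes.append("sterilization_detail_unexpected")
    applicable = record.currently_pregnant or record.postpartum_amenorrheic
    wantedness_given = record.pregnancy_wantedness not in (None, "not_applicable")
    if applicable != wantedness_given:
        codes.append("wantedness_inconsistent")
    return codes


# ---------------------------------------------------------------------------
# column dictionary
# ---------------------------------------------------------------------------


@dataclass
class ColumnDictionary:
    """Mapping from an external file's dialect onto the canonical schema.

    ``columns`` renames file columns to canonical names; ``categories``
    maps raw category codes (as read, after string conversion) to
    canonical labels, per canonical column; ``period_special_codes``
    maps special codes of ``months_since_last_period`` (e.g. DHS 994/996)
    to the states {"menopause", "before_last_birth", "never_menstruated"},
    which are folded into the boolean flags at read time.
    """

    columns: dict[str, str] = field(default_factory=dict)
    categories: dict[str, dict[str, str]] = field(default_factory=dict)
    period_special_codes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "ColumnDictionary":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnDictionary":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            columns={str(k): str(v) for k, v in (raw.get("columns") or {}).items()},
            categories={
                str(col): {str(k): str(v) for k, v in (table or {}).items()}
                for col, table in (raw.get("categories") or {}).items()
            },
            period_special_codes={
                str(k): str(v) for k, v in (raw.get("period_special_codes") or {}).items()
            },
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "columns": self.columns,
                    "categories": self.categories,
                    "period_special_codes": self.period_special_codes,
                },
                fh,
                sort_keys=True,
            )


def default_column_dictionary() -> ColumnDictionary:
    """The packaged default dictionary (DHS-style column aliases)."""
    from importlib.resources import files

    path = files("fpequity").joinpath("data/default_columns.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    return ColumnDictionary(
        columns=raw.get("columns") or {},
        categories=raw.get("categories") or {},
        period_special_codes={str(k): v for k, v in (raw.get("period_special_codes") or {}).items()},
    )


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Accounting of rows read, retained and excluded (by reason)."""

    n_input: int
    n_retained: int
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.exclusions.values()) != self.n_input:
            raise ValueError("QC accounting does not reconcile with input rows")

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_rows", self.n_input), ("retained", self.n_retained)]
        rows += [(f"excluded_{k}", v) for k, v in sorted(self.exclusions.items())]
        return pd.DataFrame(rows, columns=["item", "count"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"1", "true", "True", "TRUE", "yes"}
_FALSE_TOKENS = {"0", "false", "False", "FALSE", "no", "0.0"}


def _coerce_bool(series: pd.Series, col: str) -> pd.Series:
    def conv(v: Any) -> Any:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return pd.NA
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, np.integer, float, np.floating)):
            if float(v) in (0.0, 1.0):
                return bool(v)
            raise CategoryError(f"column {col!r}: cannot interpret {v!r} as boolean")
        s = str(v).strip()
        if s == "":
            return pd.NA
        if s in _TRUE_TOKENS:
            return True
        if s in _FALSE_TOKENS:
            return False
        raise CategoryError(f"column {col!r}: cannot interpret {v!r} as boolean")

    return series.map(conv).astype("boolean")


def read_women_table(
    path: str | Path,
    column_dictionary: ColumnDictionary | None = None,
    sep: str = ",",
) -> tuple[pd.DataFrame, QCReport]:
    """Read, map, validate and filter a woman-level microdata file.

    Returns the retained rows in canonical form plus a :class:`QCReport`
    counting exclusions by reason.  Retention mirrors the analysis
    population: women aged 15-49, currently in union, with complete
    design variables and a positive weight.

    Raises :class:`SchemaError` if a mandatory column is missing and
    :class:`CategoryError` (with the offending row index) if a category
    code cannot be mapped.
    """
    cd = column_dictionary or ColumnDictionary.identity()
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    if cd.columns:
        raw = raw.rename(columns=cd.columns)

    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"mandatory column(s) missing: {', '.join(missing_cols)}")
    for col in CANONICAL_COLUMNS:
        if col not in raw.columns:
            raw[col] = pd.NA
    df = raw.loc[:, list(CANONICAL_COLUMNS)].copy()

    # category recodes from the dictionary
    for col, table in cd.categories.items():
        if col not in df.columns:
            continue
        mapped = df[col].map(lambda v, t=table: t.get(v, v) if isinstance(v, str) else v)
        df[col] = mapped

    # special menstrual codes -> boolean flags + missing months
    if cd.period_special_codes:
        col = df["months_since_last_period"]
        special = col.map(lambda v: cd.period_special_codes.get(v) if isinstance(v, str) else None)
        meno_like = special.isin(["menopause", "never_menstruated"])
        before_birth = special == "before_last_birth"
        flag = _coerce_bool(df["menopause_hysterectomy_or_never_menstruated"],
                            "menopause_hysterectomy_or_never_menstruated")
        df["menopause_hysterectomy_or_never_menstruated"] = flag.mask(meno_like, True)
        df.loc[meno_like | before_birth, "months_since_last_period"] = pd.NA

    # dtype coercion
    for col in BOOL_COLUMNS + OPTIONAL_BOOL_COLUMNS:
        df[col] = _coerce_bool(df[col], col)
    for col in _NUMERIC_COLUMNS:
        bad = df[col].notna() & pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            idx = int(bad.idxmax())
            raise CategoryError(f"column {col!r}, row {idx}: non-numeric value {df[col][idx]!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # category validation
    for col, levels in CATEGORY_LEVELS.items():
        bad = df[col].notna() & ~df[col].isin(levels)
        if bad.any():
            idx = int(bad.idxmax())
            raise CategoryError(
                f"column {col!r}, row {idx}: unmappable category code {df[col][idx]!r}"
            )

    # exclusions, in fixed precedence order
    n_input = len(df)
    exclusions: dict[str, int] = {}

    design_missing = (
        df["stratum_id"].isna()
        | df["psu_id"].isna()
        | df["household_id"].isna()
        | df["weight"].isna()
        | (df["weight"] <= 0)
    )
    required_missing = ~design_missing & (
        df["age_years"].isna() | df[list(BOOL_COLUMNS)].isna().any(axis=1)
    )
    age_out = ~design_missing & ~required_missing & (
        (df["age_years"] < 15) | (df["age_years"] > 49)
    )
    not_in_union = ~design_missing & ~required_missing & ~age_out & ~df["in_union"].fillna(False).astype(bool)

    for reason, mask in [
        ("missing_design_variables", design_missing),
        ("missing_required_field", required_missing),
        ("age_out_of_range", age_out),
        ("not_in_union", not_in_union),
    ]:
        n = int(mask.sum())
        if n:
            exclusions[reason] = n

    keep = ~(design_missing | required_missing | age_out | not_in_union)
    out = df.loc[keep].reset_index(drop=True)
    for col in BOOL_COLUMNS:
        out[col] = out[col].astype(bool)
    out["age_years"] = out["age_years"].astype(int)
    report = QCReport(n_input=n_input, n_retained=len(out), exclusions=exclusions)
    return out, report


def write_women_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a canonical table as delimited text (booleans as 0/1)."""
    out = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    for col in BOOL_COLUMNS + OPTIONAL_BOOL_COLUMNS:
        s = out[col]
        if s.dtype == bool:
            out[col] = s.astype(int)
        else:
            out[col] = s.astype("boolean").map(lambda v: pd.NA if pd.isna(v) else int(v))
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# frame <-> record conversion
# ---------------------------------------------------------------------------


def _opt(v: Any) -> Any:
    return None if pd.isna(v) else v


def records_from_frame(df: pd.DataFrame) -> list[WomanRecord]:
    records = []
    for row in df.itertuples(index=False):
        sterilization = None
        if row.current_method in STERILIZATION_METHODS:
            sterilization = SterilizationDetail(
                age_at_sterilization=_opt(row.ster_age),
                parity_at_sterilization=_opt(row.ster_parity),
                told_means_no_more_children=_opt(row.ster_told_no_more),
                received_compensation=_opt(row.ster_received_compensation),
                compensation_amount=_opt(row.ster_compensation_amount),
                regrets=_opt(row.ster_regrets),
            )
        records.append(
            WomanRecord(
                woman_id=row.woman_id,
                stratum_id=row.stratum_id,
                psu_id=row.psu_id,
                household_id=row.household_id,
                weight=float(row.weight),
                age_years=int(row.age_years),
                in_union=bool(row.in_union),
                education_level=row.education_level,
                wealth_quintile=row.wealth_quintile,
                region_code=row.region_code,
                currently_pregnant=bool(row.currently_pregnant),
                pregnancy_wantedness=row.pregnancy_wantedness,
                fertility_preference=row.fertility_preference,
                current_method=row.current_method,
                self_reported_infecund=bool(row.self_reported_infecund),
                menopause_hysterectomy_or_never_menstruated=bool(
                    row.menopause_hysterectomy_or_never_menstruated
                ),
                months_since_last_period=_opt(row.months_since_last_period),
                postpartum_amenorrheic=bool(row.postpartum_amenorrheic),
                years_in_union=float(row.years_in_union),
                used_contraception_past_5y=bool(row.used_contraception_past_5y),
                pregnant_in_past_5y=bool(row.pregnant_in_past_5y),
                sterilization=sterilization,
                swper_items={c: _opt(getattr(row, c)) for c in SWPER_ITEM_COLUMNS},
            )
        )
    return records


def frame_from_records(records: Iterable[WomanRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        items = d.pop("swper_items")
        ster = d.pop("sterilization")
        row = dict(d)
        row.update(
            {
                "ster_age": ster["age_at_sterilization"] if ster else None,
                "ster_parity": ster["parity_at_sterilization"] if ster else None,
                "ster_told_no_more": ster["told_means_no_more_children"] if ster else None,
                "ster_received_compensation": ster["received_compensation"] if ster else None,
                "ster_compensation_amount": ster["compensation_amount"] if ster else None,
                "ster_regrets": ster["regrets"] if ster else None,
            }
        )
        for c in SWPER_ITEM_COLUMNS:
            row[c] = items.get(c)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    for col in OPTIONAL_BOOL_COLUMNS:
        df[col] = df[col].astype("boolean")
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col])
    return df
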