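"""SWPER global women's empowerment index.

The SWPER is a survey-based, individual-level empowerment index for
partnered women built from 14 questionnaire items grouped in three
domains:

* **attitude to violence** — five items asking whether wife beating is
  justified in specific situations (going out without telling the
  husband, neglecting the children, arguing, refusing sex, burning the
  food);
* **social independence** — six items: frequency of reading
  newspapers/magazines, the woman's years of schooling, age at first
  cohabitation, age at first birth, and the age and education
  differences between the woman and her husband;
* **decision-making** — three items on who usually decides about the
  woman's health care, large household purchases, and visits to family.

Each domain score is a linear combination of all 14 recoded items plus
an intercept (the loading matrix carries small cross-domain weights),
standardized against reference constants and cut into low / medium /
high categories at fixed cutpoints (half-open intervals: a score exactly
at the lower cutpoint is *medium*, at the upper cutpoint *high*).

All constants — recode tables, the 3 x 14 weight matrix, intercepts,
standardization constants and cutpoints — live in a versioned config
file that the engine treats as data.  The packaged default,
``data/swper_global_synthetic.yaml``, is a synthetic stand-in with the
documented structure (see its header); supply your own config to score
with a specific published transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .io_model import SWPER_ITEM_COLUMNS, WomanRecord

__all__ = [
    "SwperConfig",
    "SwperResult",
    "default_config",
    "load_config",
    "recode_items",
    "compute_scores",
    "categorize",
    "swper_table",
]

DOMAINS = ("attitude_to_violence", "social_independence", "decision_making")
CATEGORIES = ("low", "medium", "high")


@dataclass
class SwperConfig:
    """Scoring constants for the SWPER index (treated as data)."""

    version: str
    items: tuple[str, ...]
    recode: dict[str, dict[str, float]]
    weights: np.ndarray  # (3, 14)
    intercepts: np.ndarray  # (3,)
    centers: np.ndarray  # (3,)
    scales: np.ndarray  # (3,)
    cutpoints: np.ndarray  # (3, 2) strictly increasing per domain
    domain_items: tuple[tuple[int, ...], ...]  # support per domain
    reference_means: np.ndarray  # (14,) fill-in for missing off-support items

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        self.reference_means = np.asarray(self.reference_means, dtype=float)
        k = len(self.items)
        if self.weights.shape != (3, k):
            raise ValueError(f"weight matrix must be 3 x {k}")
        if self.intercepts.shape != (3,) or self.centers.shape != (3,) or self.scales.shape != (3,):
            raise ValueError("intercepts/centers/scales must each have 3 entries")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        if self.cutpoints.shape != (3, 2) or np.any(self.cutpoints[:, 0] >= self.cutpoints[:, 1]):
            raise ValueError("cutpoints must be a 3 x 2 strictly increasing array")
        if len(self.domain_items) != 3:
            raise ValueError("domain_items must list support for 3 domains")


@dataclass(frozen=True)
class SwperResult:
    """Domain scores and categories for one woman."""

    scores: tuple[float, float, float]
    categories: tuple[str | None, str | None, str | None]
    complete: bool


def _config_from_mapping(raw: Mapping[str, Any]) -> SwperConfig:
    items = tuple(raw["items"])
    return SwperConfig(
        version=str(raw.get("version", "unversioned")),
        items=items,
        recode={k: {str(c): float(v) for c, v in t.items()} for k, t in raw["recode"].items()},
        weights=np.array(raw["weights"], dtype=float),
        intercepts=np.array(raw["intercepts"], dtype=float),
        centers=np.array(raw["centers"], dtype=float),
        scales=np.array(raw["scales"], dtype=float),
        cutpoints=np.array(raw["cutpoints"], dtype=float),
        domain_items=tuple(tuple(ix) for ix in raw["domain_items"]),
        reference_means=np.array(raw["reference_means"], dtype=float),
    )


def load_config(path: str | Path) -> SwperConfig:
    with open(path) as fh:
        return _config_from_mapping(yaml.safe_load(fh))


_DEFAULT: SwperConfig | None = None


def default_config() -> SwperConfig:
    """The packaged (synthetic stand-in) scoring configuration."""
    global _DEFAULT
    if _DEFAULT is None:
        from importlib.resources import files

        with files("fpequity").joinpath("data/swper_global_synthetic.yaml").open() as fh:
            _DEFAULT = _config_from_mapping(yaml.safe_load(fh))
    return _DEFAULT


def _item_value(record: Any, item: str) -> Any:
    if isinstance(record, WomanRecord):
        return record.swper_items.get(item)
    if isinstance(record, Mapping):
        return record.get(item)
    return getattr(record, item)


def recode_items(record: Any, config: SwperConfig | None = None) -> np.ndarray:
    """Recode one woman's raw items into the 14-vector the scoring uses.

    Missing raw items propagate as NaN.  A raw category string absent
    from its recode table is a hard error.
    """
    config = config or default_config()
    out = np.full(len(config.items), np.nan)
    for j, item in enumerate(config.items):
        v = _item_value(record, item)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            continue
        table = config.recode.get(item)
        if table is not None:
            key = str(v)
            if key not in table:
                raise ValueError(f"item {item!r}: category {v!r} not in recode table")
            out[j] = table[key]
        else:
            out[j] = float(v)
    return out


def compute_scores(items: np.ndarray, config: SwperConfig | None = None) -> np.ndarray:
    """Standardized domain scores from a recoded item vector.

    score_d = (intercept_d + w_d . items - center_d) / scale_d.  A
    domain's score is missing when any item in its support is missing;
    missing off-support items fall back to the config's reference means
    (their cross-weights are small).
    """
    config = config or default_config()
    items = np.asarray(items, dtype=float)
    filled = np.where(np.isnan(items), config.reference_means, items)
    raw = config.intercepts + config.weights @ filled
    scores = (raw - config.centers) / config.scales
    for d, support in enumerate(config.domain_items):
        if np.isnan(items[list(support)]).any():
            scores[d] = np.nan
    return scores


def categorize(scores: np.ndarray, config: SwperConfig | None = None) -> tuple[str | None, ...]:
    """Cut each domain score at the config cutpoints (half-open):
    low iff s < cut1; medium iff cut1 <= s < cut2; high iff s >= cut2."""
    config = config or default_config()
    cats: list[str | None] = []
    for d, s in enumerate(np.asarray(scores, dtype=float)):
        if np.isnan(s):
            cats.append(None)
        elif s < config.cutpoints[d, 0]:
            cats.append("low")
        elif s < config.cutpoints[d, 1]:
            cats.append("medium")
        else:
            cats.append("high")
    return tuple(cats)


def score_record(record: Any, config: SwperConfig | None = None) -> SwperResult:
    config = config or default_config()
    items = recode_items(record, config)
    scores = compute_scores(items, config)
    return SwperResult(
        scores=tuple(scores),
        categories=categorize(scores, config),
        complete=bool(not np.isnan(items).any()),
    )


#: columns emitted by :func:`swper_table`
SWPER_OUTPUT_COLUMNS = (
    "woman_id",
    "swper_attitude_to_violence",
    "swper_social_independence",
    "swper_decision_making",
    "swper_cat_attitude_to_violence",
    "swper_cat_social_independence",
    "swper_cat_decision_making",
    "swper_complete",
)


def swper_table(df: pd.DataFrame, config: SwperConfig | None = None) -> pd.DataFrame:
    """Vectorized scoring of a canonical table (one row per woman).

    Equivalent to applying :func:`score_record` row by row (asserted in
    the test suite) but recodes column-wise and scores with one matrix
    product.
    """
    config = config or default_config()
    n = len(df)
    X = np.full((n, len(config.items)), np.nan)
    for j, item in enumerate(config.items):
        col = df[item]
        table = config.recode.get(item)
        if table is not None:
            mapped = col.map(lambda v, t=table: t.get(str(v)) if not pd.isna(v) else np.nan)
            bad = col.notna() & mapped.isna()
            if bad.any():
                idx = int(bad.idxmax())
                raise ValueError(
                    f"item {item!r}, row {idx}: category {col[idx]!r} not in recode table"
                )
            X[:, j] = mapped.to_numpy(dtype=float)
        else:
            X[:, j] = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)

    filled = np.where(np.isnan(X), config.reference_means, X)
    raw = filled @ config.weights.T + config.intercepts
    scores = (raw - config.centers) / config.scales
    for d, support in enumerate(config.domain_items):
        scores[np.isnan(X[:, list(support)]).any(axis=1), d] = np.nan

    out = pd.DataFrame({"woman_id": df["woman_id"].to_numpy()})
    for d, name in enumerate(DOMAINS):
        s = scores[:, d]
        out[f"swper_{name}"] = s
        cat = np.select(
            [np.isnan(s), s < config.cutpoints[d, 0], s < config.cutpoints[d, 1]],
            [None, "low", "medium"],
            default="high",
        )
        out[f"swper_cat_{name}"] = cat
    out["swper_complete"] = ~np.isnan(X).any(axis=1)
    return out
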