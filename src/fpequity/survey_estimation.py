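"""Design-based estimation for stratified two-stage cluster surveys.

Proportions (and means) are estimated as ratio estimators

    p_hat = sum_i w_i y_i d_i / sum_i w_i d_i

over a domain indicator ``d`` with sampling weights ``w``.  Variances
use Taylor linearization with the ultimate-cluster (with-replacement
first stage) approximation: the linearized value u_i = w_i d_i (y_i -
p_hat) / W is totalled per PSU and the variance is the usual stratified
between-PSU sum

    var = sum_h  n_h / (n_h - 1) * sum_c (z_hc - zbar_h)^2 .

Domain (subpopulation) estimation is performed by zero-weighting
out-of-domain records — never by subsetting before variance estimation —
so PSUs without domain members still contribute their (zero) totals and
subpopulation standard errors are correct.

Degrees of freedom follow the survey convention #PSUs - #strata,
restricted to strata containing domain members.  Confidence intervals
are Wald intervals on the logit scale, back-transformed (a DHS-style
choice that respects [0, 1]); a degenerate estimate (p in {0, 1}) or a
zero standard error yields the degenerate interval [p, p].  Strata left
with a single PSU are handled per the design's lonely-PSU policy
("collapse" merges them with the neighbouring stratum in sorted order;
"error" raises).  No finite-population correction is applied
(with-replacement approximation, standard DHS practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurveyDesign",
    "EstimateRow",
    "EstimationError",
    "weighted_proportion",
    "weighted_mean",
    "share_table",
    "stratified_estimates",
    "rows_to_frame",
]

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    """Raised for empty domains or unusable designs."""


@dataclass(frozen=True)
class SurveyDesign:
    """Names of the design columns plus the lonely-PSU policy."""

    stratum: str = "stratum_id"
    psu: str = "psu_id"
    weight: str = "weight"
    lonely_psu: str = "collapse"  # collapse | error


@dataclass(frozen=True)
class EstimateRow:
    """A survey-weighted estimate with its uncertainty."""

    domain_label: str
    outcome_label: str
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    df: int
    n_unweighted: int
    n_weighted: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "domain": self.domain_label,
            "outcome": self.outcome_label,
            "p_hat": self.p_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "df": self.df,
            "n_unweighted": self.n_unweighted,
            "n_weighted": self.n_weighted,
        }


ESTIMATE_COLUMNS = ("domain", "outcome", "p_hat", "se", "ci_low", "ci_high",
                    "df", "n_unweighted", "n_weighted")


def rows_to_frame(rows: Iterable[EstimateRow], extra: dict[str, list] | None = None) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in rows], columns=list(ESTIMATE_COLUMNS))
    if extra:
        for k, v in extra.items():
            df.insert(0, k, v)
    return df


def _as_bool_array(df: pd.DataFrame, spec: Any) -> np.ndarray:
    if spec is None:
        return np.ones(len(df), dtype=bool)
    if callable(spec):
        spec = spec(df)
    if isinstance(spec, str):
        spec = df[spec]
    arr = np.asarray(spec)
    if arr.dtype != bool:
        arr = arr.astype(bool)
    if arr.shape != (len(df),):
        raise EstimationError("indicator/domain must align with the table rows")
    return arr


def _collapse_lonely(psu_stratum: pd.Series, policy: str) -> pd.Series:
    """Reassign strata containing a single PSU to a neighbouring stratum."""
    counts = psu_stratum.value_counts()
    lonely = sorted(counts.index[counts == 1])
    if not lonely:
        return psu_stratum
    if policy == "error":
        raise EstimationError(f"single-PSU stratum/strata: {lonely}")
    if policy != "collapse":
        raise EstimationError(f"unknown lonely-PSU policy {policy!r}")
    order = sorted(counts.index)
    mapping = {}
    for s in lonely:
        i = order.index(s)
        # merge with the previous stratum in sorted order, else the next
        target = order[i - 1] if i > 0 else order[i + 1] if len(order) > 1 else s
        # chase chains so two adjacent lonely strata merge together
        while target in mapping:
            target = mapping[target]
        if target == s:
            raise EstimationError("design has a single PSU overall; variance undefined")
        mapping[s] = target
        logger.info("lonely PSU: collapsing stratum %r into %r", s, target)
    return psu_stratum.replace(mapping)


def _taylor(
    df: pd.DataFrame,
    y: np.ndarray,
    domain: np.ndarray,
    design: SurveyDesign,
    domain_label: str,
    outcome_label: str,
    logit_ci: bool,
    alpha: float = 0.05,
) -> EstimateRow:
    w = df[design.weight].to_numpy(dtype=float)
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise EstimationError("weights must be positive and finite")
    d = domain.astype(float)
    n_dom = int(domain.sum())
    if n_dom == 0:
        raise EstimationError(f"empty domain {domain_label!r}")
    wd = w * d
    W = wd.sum()
    yv = np.where(domain, np.asarray(y, dtype=float), 0.0)
    p = float((wd * yv).sum() / W)

    u = wd * (yv - p) / W
    g = pd.DataFrame(
        {"stratum": df[design.stratum].to_numpy(), "psu": df[design.psu].to_numpy(), "u": u}
    )
    psu_tot = g.groupby(["stratum", "psu"], sort=True)["u"].sum()
    psu_stratum = psu_tot.index.get_level_values("stratum").to_series(index=psu_tot.index)
    psu_stratum = _collapse_lonely(psu_stratum, design.lonely_psu)

    z = pd.DataFrame({"stratum": psu_stratum.to_numpy(), "z": psu_tot.to_numpy()})
    var = 0.0
    for _, grp in z.groupby("stratum", sort=True):
        n_h = len(grp)
        if n_h < 2:
            raise EstimationError("stratum with a single PSU after collapsing")
        zc = grp["z"].to_numpy()
        var += n_h / (n_h - 1) * float(((zc - zc.mean()) ** 2).sum())
    se = float(np.sqrt(var))

    # df over strata containing domain members
    gd = pd.DataFrame(
        {
            "stratum": df[design.stratum].to_numpy(),
            "psu": df[design.psu].to_numpy(),
            "d": domain,
        }
    )
    in_dom = gd.groupby("stratum", sort=True)["d"].any()
    dom_strata = set(in_dom.index[in_dom])
    psus_in_dom_strata = gd[gd["stratum"].isin(dom_strata)].groupby(["stratum", "psu"]).ngroups
    dof = max(int(psus_in_dom_strata - len(dom_strata)), 1)

    if se == 0.0 or (logit_ci and (p <= 0.0 or p >= 1.0)):
        lo = hi = p
    else:
        t = float(stats.t.ppf(1 - alpha / 2, dof))
        if logit_ci:
            l = np.log(p / (1 - p))
            se_l = se / (p * (1 - p))
            lo = float(1 / (1 + np.exp(-(l - t * se_l))))
            hi = float(1 / (1 + np.exp(-(l + t * se_l))))
        else:
            lo = p - t * se
            hi = p + t * se
    return EstimateRow(
        domain_label=domain_label,
        outcome_label=outcome_label,
        p_hat=p,
        se=se,
        ci_low=lo,
        ci_high=hi,
        df=dof,
        n_unweighted=n_dom,
        n_weighted=float(W),
    )


def weighted_proportion(
    df: pd.DataFrame,
    indicator: Any,
    domain: Any = None,
    design: SurveyDesign | None = None,
    domain_label: str = "all",
    outcome_label: str = "proportion",
) -> EstimateRow:
    """Survey-weighted proportion of ``indicator`` within ``domain``.

    ``indicator`` and ``domain`` may be column names, boolean arrays, or
    callables of the frame.
    """
    design = design or SurveyDesign()
    y = _as_bool_array(df, indicator)
    d = _as_bool_array(df, domain)
    return _taylor(df, y, d, design, domain_label, outcome_label, logit_ci=True)


def weighted_mean(
    df: pd.DataFrame,
    values: Any,
    domain: Any = None,
    design: SurveyDesign | None = None,
    domain_label: str = "all",
    outcome_label: str = "mean",
) -> EstimateRow:
    """Survey-weighted mean of a numeric column within a domain (plain
    t-based Wald interval; same linearized variance as the proportion)."""
    design = design or SurveyDesign()
    if isinstance(values, str):
        values = df[values]
    y = np.asarray(values, dtype=float)
    d = _as_bool_array(df, domain)
    if np.isnan(y[d]).any():
        d = d & ~np.isnan(y)
        if not d.any():
            raise EstimationError("domain has no non-missing values")
    y = np.where(np.isnan(y), 0.0, y)
    return _taylor(df, y, d, design, domain_label, outcome_label, logit_ci=False)


def share_table(
    df: pd.DataFrame,
    class_column: str,
    domain: Any = None,
    design: SurveyDesign | None = None,
    levels: Sequence[str] | None = None,
    domain_label: str = "users",
) -> list[EstimateRow]:
    """One EstimateRow per level of a categorical column: the shares of
    an exhaustive partition of the domain (point estimates sum to 1)."""
    design = design or SurveyDesign()
    d = _as_bool_array(df, domain)
    col = df[class_column]
    if levels is None:
        levels = sorted(col[d].dropna().unique())
    rows = []
    for level in levels:
        rows.append(
            weighted_proportion(
                df,
                (col == level).to_numpy(),
                d,
                design,
                domain_label=domain_label,
                outcome_label=str(level),
            )
        )
    return rows


def stratified_estimates(
    df: pd.DataFrame,
    indicator: Any,
    stratifier: str,
    domain: Any = None,
    design: SurveyDesign | None = None,
    levels: Sequence[str] | None = None,
    outcome_label: str = "proportion",
) -> pd.DataFrame:
    """Estimate an indicator separately for each level of a stratifier.

    Levels with an empty domain are flagged with NaN estimates and
    ``n_unweighted = 0`` rather than silently dropped.  Unknown levels
    passed explicitly raise.
    """
    design = design or SurveyDesign()
    y = _as_bool_array(df, indicator)
    d = _as_bool_array(df, domain)
    col = df[stratifier]
    present = set(col.dropna().unique())
    if levels is None:
        levels = sorted(present)
    else:
        unknown = [lv for lv in levels if lv not in present]
        if unknown:
            raise EstimationError(f"stratifier {stratifier!r} has no level(s) {unknown}")
    rows = []
    for level in levels:
        d_level = d & (col == level).to_numpy()
        if not d_level.any():
            rows.append(
                EstimateRow(str(level), outcome_label, np.nan, np.nan, np.nan, np.nan, 0, 0, 0.0)
            )
            continue
        rows.append(
            _taylor(df, y, d_level, design, str(level), outcome_label, logit_ci=True)
        )
    out = rows_to_frame(rows)
    out.insert(0, "stratifier", stratifier)
    out = out.rename(columns={"domain": "level"})
    return out
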