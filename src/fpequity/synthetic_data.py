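"""Synthetic NFHS-like survey microdata with known census truth.

Emulates the record structure and sampling design of a large national
family-health survey of partnered women aged 15-49: a stratified
two-stage design in which primary sampling units (PSUs) are drawn with
probability proportional to size within strata and a fixed take of 22
households is selected systematically within each sampled PSU.

The generative model is deliberately built from *discrete* covariate
cells so that population quantities have a closed form
(:func:`expected_truth`):

* region = stratum; household wealth quintile depends on region;
  education depends on wealth; a three-level latent empowerment class
  depends on education and drives two continuous latent factors
  (gender attitudes, social independence) used to draw the 14 SWPER
  items;
* current contraceptive method follows a multinomial logit in age band,
  education, wealth and empowerment class, calibrated so that the
  census demand-for-family-planning-satisfied (DFPS) is ~0.72 with a
  permanent-method share among users of ~0.76, a permanent share rising
  with age and a SARC share rising with wealth, education and
  empowerment (structural features the pipeline's reports should
  recover);
* for non-users, fecundity status (with the infecundity rule that
  applies), pregnancy, post-partum amenorrhea, pregnancy wantedness and
  fertility preference are drawn from age-band tables, and the raw
  questionnaire fields are then filled in so that the classification
  rules recover the drawn state exactly;
* sterilized women receive age/parity at sterilization, an indicator of
  having been told the procedure is permanent, monetary compensation
  (probability and amount depending on wealth) and regret (depending on
  parity at sterilization).

Everything is deterministic given (spec, seed); census generation and
survey draws consume independent seeds so one census supports many
replicate draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .io_model import CANONICAL_COLUMNS, SWPER_ITEM_COLUMNS
from . import swper as swper_mod

__all__ = [
    "PopulationSpec",
    "DesignParams",
    "CensusTruth",
    "generate_census",
    "draw_survey",
    "replicate_study",
    "expected_truth",
]

AGE_BANDS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49")
METHOD_CHOICES = ("none", "traditional", "pill", "condom", "injectable", "iud",
                  "female_sterilization", "male_sterilization")
_CLASS_OF = {"pill": "SARC", "condom": "SARC", "injectable": "SARC", "iud": "LARC",
             "female_sterilization": "PERMANENT", "male_sterilization": "PERMANENT"}


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class PopulationSpec:
    """Parameters of the synthetic population (the study conditions).

    Method-choice coefficients are per-method ``(alpha, b_age, b_edu,
    b_wealth, b_emp)`` with centred integer covariates: age band index
    - 3, education level - 1, wealth quintile index - 2, empowerment
    class - 1.  ``none`` is the reference category.
    """

    n_strata: int = 8
    psus_per_stratum: int = 400
    psu_household_range: tuple[int, int] = (40, 80)
    women_per_household_probs: tuple[float, ...] = (0.75, 0.25)  # P(1), P(2)

    age_band_probs: tuple[float, ...] = (0.10, 0.16, 0.17, 0.16, 0.15, 0.14, 0.12)
    #: log-linear tilt of the wealth distribution per region (cycled)
    wealth_tilt_by_region: tuple[float, ...] = (-0.35, -0.2, -0.1, 0.0, 0.0, 0.1, 0.2, 0.35)
    #: P(education level | wealth quintile), rows Q1..Q5
    education_given_wealth: tuple[tuple[float, ...], ...] = (
        (0.55, 0.30, 0.15),
        (0.42, 0.33, 0.25),
        (0.30, 0.33, 0.37),
        (0.18, 0.30, 0.52),
        (0.08, 0.22, 0.70),
    )
    #: P(empowerment class | education), rows none/primary/secondary+
    empowerment_given_education: tuple[tuple[float, ...], ...] = (
        (0.55, 0.33, 0.12),
        (0.38, 0.40, 0.22),
        (0.18, 0.42, 0.40),
    )
    latent_means: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    latent_sd: float = 0.6

    #: method -> (alpha, b_age, b_edu, b_wealth, b_emp); "none" is baseline
    method_coefficients: dict[str, tuple[float, float, float, float, float]] = field(
        default_factory=lambda: {
            "traditional": (-2.35, 0.15, 0.05, 0.00, 0.05),
            "pill": (-2.20, -0.10, 0.15, 0.10, 0.15),
            "condom": (-1.95, -0.15, 0.30, 0.25, 0.25),
            "injectable": (-5.30, 0.00, 0.05, 0.05, 0.05),
            "iud": (-3.15, -0.05, 0.25, 0.20, 0.25),
            "female_sterilization": (0.05, 0.85, -0.15, 0.05, -0.20),
            "male_sterilization": (-5.20, 0.30, 0.00, 0.00, 0.00),
        }
    )

    #: P(infecund | non-user, age band) and the split over rules 1-4
    infecund_prob_by_band: tuple[float, ...] = (0.02, 0.03, 0.05, 0.08, 0.14, 0.28, 0.50)
    infecund_reason_probs: tuple[float, ...] = (0.30, 0.10, 0.40, 0.20)
    #: P(currently pregnant | fecund non-user, age band)
    pregnant_prob_by_band: tuple[float, ...] = (0.20, 0.24, 0.20, 0.13, 0.07, 0.03, 0.01)
    #: P(postpartum amenorrheic | fecund, non-pregnant non-user, age band)
    ppa_prob_by_band: tuple[float, ...] = (0.10, 0.12, 0.10, 0.07, 0.04, 0.02, 0.01)
    #: wantedness of the current/last pregnancy (then, later, not at all)
    wantedness_probs: tuple[float, ...] = (0.72, 0.18, 0.10)
    #: fertility preference of fecund, non-pregnant, non-amenorrheic
    #: non-users (within 2y, after 2y, no more, unsure), per age band
    preference_probs_by_band: tuple[tuple[float, ...], ...] = (
        (0.55, 0.25, 0.15, 0.05),
        (0.45, 0.25, 0.25, 0.05),
        (0.35, 0.18, 0.42, 0.05),
        (0.20, 0.10, 0.65, 0.05),
        (0.10, 0.05, 0.80, 0.05),
        (0.05, 0.02, 0.88, 0.05),
        (0.03, 0.01, 0.91, 0.05),
    )

    # sterilization-detail model
    ster_age_mean: float = 25.8
    ster_age_sd: float = 4.5
    ster_parity_band_probs: tuple[float, ...] = (0.033, 0.434, 0.294, 0.239)
    ster_not_told_prob: float = 0.208
    ster_compensation_prob_by_wealth: tuple[float, ...] = (0.763, 0.714, 0.661, 0.572, 0.409)
    ster_compensation_mean_by_wealth: tuple[float, ...] = (659.0, 637.0, 692.0, 737.0, 784.0)
    ster_compensation_sd: float = 160.0
    ster_regret_prob_by_parity_band: tuple[float, ...] = (0.118, 0.075, 0.065, 0.058)

    # item non-response knobs (default: small, realistic; set to 0 for
    # fully complete data)
    swper_missing_rate: float = 0.01
    age_first_birth_missing_rate: float = 0.06

    def validate(self) -> None:
        if self.n_strata < 1 or self.psus_per_stratum < 1:
            raise ValueError("need at least one stratum and one PSU per stratum")
        lo, hi = self.psu_household_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid psu_household_range")
        for name in (
            "age_band_probs",
            "women_per_household_probs",
            "infecund_reason_probs",
            "wantedness_probs",
            "ster_parity_band_probs",
        ):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for table in (self.education_given_wealth, self.empowerment_given_education,
                      self.preference_probs_by_band):
            for row in table:
                r = np.asarray(row, dtype=float)
                if np.any(r < 0) or abs(r.sum() - 1.0) > 1e-9:
                    raise ValueError("conditional probability rows must sum to 1")
        for name in ("infecund_prob_by_band", "pregnant_prob_by_band", "ppa_prob_by_band"):
            p = np.asarray(getattr(self, name), dtype=float)
            if len(p) != 7 or np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} must be 7 probabilities")
        for m in self.method_coefficients:
            if m not in METHOD_CHOICES or m == "none":
                raise ValueError(f"unknown method in coefficients: {m!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PopulationSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if f.name == "method_coefficients":
                    v = {k: tuple(t) for k, t in v.items()}
                kwargs[f.name] = v
        spec = cls(**kwargs)
        spec.validate()
        return spec

    def to_yaml(self, path: str) -> None:
        def plain(v: Any) -> Any:
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        with open(path, "w") as fh:
            yaml.safe_dump({f.name: plain(getattr(self, f.name))
                            for f in dataclasses.fields(self)}, fh, sort_keys=True)


@dataclass(frozen=True)
class DesignParams:
    """Two-stage sample design: PPS PSUs, fixed household take."""

    n_psus_per_stratum: int = 23
    households_per_psu: int = 22
    normalize_weights: bool = True


@dataclass
class CensusTruth:
    """Population values computed by direct counting over the census."""

    n_women: int
    dfps: float
    class_shares: dict[str, float]  # SARC/LARC/PERMANENT among modern users
    method_shares: dict[str, float]  # specific methods among modern users
    dfps_by: dict[str, dict[str, float]]  # stratifier -> level -> DFPS
    permanent_share_by_age: dict[str, float]
    sarc_share_by_wealth: dict[str, float]
    sterilization: dict[str, Any]

    def gap(self, stratifier: str, level_a: str, level_b: str) -> float:
        t = self.dfps_by[stratifier]
        return 100.0 * (t[level_a] - t[level_b])


# ---------------------------------------------------------------------------
# census generation
# ---------------------------------------------------------------------------


def _method_probs(spec: PopulationSpec, a: np.ndarray, ed: np.ndarray,
                  q: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Multinomial-logit choice probabilities, rows sum to 1."""
    ac, edc, qc, ec = a - 3, ed - 1, q - 2, e - 1
    eta = np.zeros((len(a), len(METHOD_CHOICES)))
    for j, m in enumerate(METHOD_CHOICES):
        if m == "none":
            continue
        al, ba, be, bq, bm = spec.method_coefficients[m]
        eta[:, j] = al + ba * ac + be * edc + bq * qc + bm * ec
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _choice(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized row-wise categorical draw."""
    u = rng.random(len(probs))
    return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)


def _wealth_probs(spec: PopulationSpec, stratum_idx: np.ndarray) -> np.ndarray:
    tilt = np.asarray(spec.wealth_tilt_by_region, dtype=float)
    g = tilt[stratum_idx % len(tilt)]
    qs = np.arange(5) - 2
    p = np.exp(g[:, None] * qs[None, :])
    return p / p.sum(axis=1, keepdims=True)


def generate_census(
    spec: PopulationSpec, seed: int, return_internal: bool = False
) -> tuple[pd.DataFrame, CensusTruth] | tuple[pd.DataFrame, CensusTruth, pd.DataFrame]:
    """Generate the full population frame and its census truth.

    Returns ``(census, truth)``; with ``return_internal=True`` also the
    frame of generator-internal states (need, fecundity, class) used for
    direct-counting truth, for cross-checks against the classifier.
    """
    spec.validate()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    # --- frame: strata > PSUs > households > women -------------------------
    n_psu = spec.n_strata * spec.psus_per_stratum
    lo, hi = spec.psu_household_range
    psu_households = rng.integers(lo, hi + 1, size=n_psu)
    psu_stratum = np.repeat(np.arange(spec.n_strata), spec.psus_per_stratum)

    hh_psu = np.repeat(np.arange(n_psu), psu_households)
    n_hh = len(hh_psu)
    p1 = spec.women_per_household_probs[0]
    women_per_hh = np.where(rng.random(n_hh) < p1, 1, 2)
    woman_hh = np.repeat(np.arange(n_hh), women_per_hh)
    n = len(woman_hh)

    stratum_idx = psu_stratum[hh_psu[woman_hh]]
    psu_idx = hh_psu[woman_hh]
    # household index within PSU for readable ids
    hh_within = np.concatenate([np.arange(c) for c in psu_households])

    # --- covariates --------------------------------------------------------
    band = _choice(rng, np.tile(np.asarray(spec.age_band_probs), (n, 1)))
    age = 15 + 5 * band + rng.integers(0, 5, size=n)
    q = _choice(rng, _wealth_probs(spec, stratum_idx))
    ed = _choice(rng, np.asarray(spec.education_given_wealth)[q])
    e = _choice(rng, np.asarray(spec.empowerment_given_education)[ed])
    mu = np.asarray(spec.latent_means)
    f1 = rng.normal(mu[e], spec.latent_sd)
    f2 = rng.normal(mu[e], spec.latent_sd) + 0.3 * (ed - 1)

    # --- method choice -----------------------------------------------------
    method_idx = _choice(rng, _method_probs(spec, band, ed, q, e))
    method = np.asarray(METHOD_CHOICES)[method_idx]
    user = method != "none"
    modern = user & (method != "traditional")

    # --- reproductive state for non-users ----------------------------------
    nonuser = ~user
    infec_p = np.asarray(spec.infecund_prob_by_band)[band]
    infecund = nonuser & (rng.random(n) < infec_p)
    reason_idx = np.where(
        infecund, _choice(rng, np.tile(np.asarray(spec.infecund_reason_probs), (n, 1))), -1
    )
    fecund_nonuser = nonuser & ~infecund
    pregnant = fecund_nonuser & (rng.random(n) < np.asarray(spec.pregnant_prob_by_band)[band])
    ppa = (
        fecund_nonuser
        & ~pregnant
        & (rng.random(n) < np.asarray(spec.ppa_prob_by_band)[band])
    )
    want_idx = _choice(rng, np.tile(np.asarray(spec.wantedness_probs), (n, 1)))
    wantedness = np.where(
        pregnant | ppa,
        np.asarray(("wanted_then", "wanted_later", "wanted_not_at_all"))[want_idx],
        "not_applicable",
    )
    pref_idx = _choice(rng, np.asarray(spec.preference_probs_by_band)[band])
    plain_nonuser = fecund_nonuser & ~pregnant & ~ppa
    preference = np.where(
        plain_nonuser,
        np.asarray(("wants_within_2y", "wants_after_2y", "wants_no_more", "unsure"))[pref_idx],
        "not_applicable",
    )
    # users carry a preference too (ignored by the classifier; sterilized
    # women want no more children by construction)
    user_pref = np.where(
        np.isin(method, ("female_sterilization", "male_sterilization")),
        "wants_no_more",
        np.asarray(("wants_no_more", "wants_after_2y", "wants_within_2y"))[
            _choice(rng, np.tile(np.array([0.6, 0.25, 0.15]), (n, 1)))
        ],
    )
    preference = np.where(user, user_pref, preference)

    # --- raw questionnaire fields consistent with the drawn state ----------
    # rounded at draw time: the stored value is what the classifier sees
    years_in_union = np.round(np.clip(rng.uniform(0.0, np.maximum(age - 14, 1.0)), 0.0, 34.0), 1)
    used_past5 = np.zeros(n, dtype=bool)
    preg_past5 = np.zeros(n, dtype=bool)
    months = rng.integers(0, 7, size=n).astype(float)
    self_rep = np.zeros(n, dtype=bool)
    meno = np.zeros(n, dtype=bool)

    used_past5[user] = True
    # fecund non-users married >= 5y must have a recent pregnancy or use,
    # otherwise rule 1 would misfire
    long_union = fecund_nonuser & (years_in_union >= 5)
    preg_past5[long_union] = True

    r1 = infecund & (reason_idx == 0)
    r2 = infecund & (reason_idx == 1)
    r3 = infecund & (reason_idx == 2)
    r4 = infecund & (reason_idx == 3)
    years_in_union[r1] = np.round(rng.uniform(5.0, np.maximum(age[r1] - 15, 6.0)), 1)
    used_past5[r2 | r3 | r4] = True  # blocks rule 1 for higher-rule draws
    self_rep[r2] = True
    meno[r3] = True
    months[r3] = np.nan
    months[r4] = rng.integers(7, 25, size=int(r4.sum())).astype(float)
    months[pregnant] = rng.integers(0, 7, size=int(pregnant.sum())).astype(float)
    months[ppa] = rng.integers(0, 13, size=int(ppa.sum())).astype(float)

    # --- SWPER items --------------------------------------------------------
    items: dict[str, np.ndarray] = {}
    viol_levels = np.asarray(("justified", "dont_know", "not_justified"))
    for j, col in enumerate(SWPER_ITEM_COLUMNS[:5]):
        p_not = _expit(1.3 * f1 + 0.3 + 0.05 * j)
        p_dk = 0.05 * np.ones(n)
        p_just = np.clip(1 - p_not - p_dk, 0.0, 1.0)
        probs = np.stack([p_just, p_dk, p_not], axis=1)
        probs /= probs.sum(axis=1, keepdims=True)
        items[col] = viol_levels[_choice(rng, probs)]
    p_week = _expit(f2 - 0.5)
    p_none = _expit(-f2 - 0.5)
    probs = np.stack([p_none, np.clip(1 - p_none - p_week, 0, 1), p_week], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    items["freq_reading"] = np.asarray(READING := ("not_at_all", "less_than_weekly", "weekly"))[
        _choice(rng, probs)
    ]
    edu_years = np.select(
        [ed == 0, ed == 1],
        [rng.integers(0, 2, n), rng.integers(2, 8, n)],
        default=np.clip(rng.integers(8, 13, n) + np.round(f2).astype(int), 8, 17),
    ).astype(float)
    items["education_years"] = edu_years
    cohab = np.clip(np.round(rng.normal(20.0 + 2.0 * f2, 2.5)), 13, None)
    cohab = np.minimum(cohab, age)
    items["age_first_cohabitation"] = cohab.astype(float)
    fbirth = np.minimum(cohab + 1 + np.round(rng.exponential(1.5, n)), age)
    items["age_first_birth"] = fbirth.astype(float)
    items["age_difference"] = np.round(np.clip(rng.normal(-4.5 + 1.2 * f2, 2.5), -15, 10))
    items["education_difference"] = np.round(np.clip(rng.normal(-2.0 + 1.5 * f2, 2.5), -15, 15))
    f3 = 0.5 * f1 + 0.5 * f2 + rng.normal(0, 0.5, n)
    dec_levels = np.asarray(("husband_or_other", "joint", "respondent_alone"))
    for col in SWPER_ITEM_COLUMNS[11:14]:
        p_h = _expit(-f3 - 0.3)
        p_a = _expit(f3 - 1.2)
        probs = np.stack([p_h, np.clip(1 - p_h - p_a, 0, 1), p_a], axis=1)
        probs /= probs.sum(axis=1, keepdims=True)
        items[col] = dec_levels[_choice(rng, probs)]

    # item non-response
    obj_items = {}
    for col in SWPER_ITEM_COLUMNS:
        rate = (
            spec.age_first_birth_missing_rate
            if col == "age_first_birth"
            else spec.swper_missing_rate
        )
        vals = items[col].astype(object)
        if rate > 0:
            vals[rng.random(n) < rate] = None
        obj_items[col] = vals

    # --- sterilization details ---------------------------------------------
    ster = np.isin(method, ("female_sterilization", "male_sterilization"))
    n_s = int(ster.sum())
    ster_age = np.full(n, np.nan)
    ster_parity = np.full(n, np.nan)
    ster_told = np.full(n, None, dtype=object)
    ster_comp = np.full(n, None, dtype=object)
    ster_amount = np.full(n, np.nan)
    ster_regret = np.full(n, None, dtype=object)
    if n_s:
        a_s = np.clip(np.round(rng.normal(spec.ster_age_mean, spec.ster_age_sd, n_s)), 16, None)
        ster_age[ster] = np.minimum(a_s, age[ster])
        pband = _choice(rng, np.tile(np.asarray(spec.ster_parity_band_probs), (n_s, 1)))
        parity = np.select(
            [pband == 0, pband == 1, pband == 2],
            [rng.integers(0, 2, n_s), np.full(n_s, 2), np.full(n_s, 3)],
            default=4 + rng.poisson(0.8, n_s),
        )
        ster_parity[ster] = parity
        ster_told[ster] = rng.random(n_s) >= spec.ster_not_told_prob
        comp_p = np.asarray(spec.ster_compensation_prob_by_wealth)[q[ster]]
        comp = rng.random(n_s) < comp_p
        ster_comp[ster] = comp
        amounts = np.clip(
            rng.normal(
                np.asarray(spec.ster_compensation_mean_by_wealth)[q[ster]],
                spec.ster_compensation_sd,
            ),
            0.0,
            None,
        )
        amt = np.full(n_s, np.nan)
        amt[comp] = np.round(amounts[comp], 0)
        ster_amount[ster] = amt
        regret_p = np.asarray(spec.ster_regret_prob_by_parity_band)[pband]
        ster_regret[ster] = rng.random(n_s) < regret_p

    # --- assemble the canonical frame --------------------------------------
    region = np.asarray([f"R{k + 1:02d}" for k in range(spec.n_strata)])[stratum_idx]
    census = pd.DataFrame(
        {
            "woman_id": [f"W{i:07d}" for i in range(n)],
            "stratum_id": np.asarray([f"S{k + 1:02d}" for k in range(spec.n_strata)])[stratum_idx],
            "psu_id": np.asarray([f"P{j:05d}" for j in range(n_psu)])[psu_idx],
            "household_id": [
                f"P{p:05d}-H{h:04d}" for p, h in zip(psu_idx, hh_within[woman_hh])
            ],
            "weight": 1.0,
            "age_years": age,
            "in_union": True,
            "education_level": np.asarray(("none", "primary", "secondary_or_higher"))[ed],
            "wealth_quintile": np.asarray(("Q1", "Q2", "Q3", "Q4", "Q5"))[q],
            "region_code": region,
            "currently_pregnant": pregnant,
            "pregnancy_wantedness": wantedness,
            "fertility_preference": preference,
            "current_method": method,
            "self_reported_infecund": self_rep,
            "menopause_hysterectomy_or_never_menstruated": meno,
            "months_since_last_period": months,
            "postpartum_amenorrheic": ppa,
            "years_in_union": years_in_union,
            "used_contraception_past_5y": used_past5,
            "pregnant_in_past_5y": preg_past5,
            "ster_age": ster_age,
            "ster_parity": ster_parity,
            "ster_told_no_more": pd.array(ster_told, dtype="boolean"),
            "ster_received_compensation": pd.array(ster_comp, dtype="boolean"),
            "ster_compensation_amount": ster_amount,
            "ster_regrets": pd.array(ster_regret, dtype="boolean"),
        }
    )
    for col in SWPER_ITEM_COLUMNS:
        census[col] = obj_items[col]
    census = census.loc[:, list(CANONICAL_COLUMNS)]

    # --- internal truth states ----------------------------------------------
    in_need = (
        modern
        | (method == "traditional")
        | ((pregnant | ppa) & np.isin(wantedness, ("wanted_later", "wanted_not_at_all")))
        | (
            plain_nonuser
            & np.isin(preference, ("wants_after_2y", "wants_no_more", "unsure"))
        )
    )
    need = np.where(
        modern,
        "met_modern",
        np.where(
            method == "traditional",
            "met_traditional",
            np.where(in_need, "unmet_need", "no_need"),
        ),
    )
    action_class = np.asarray([_CLASS_OF.get(m, "not_applicable") for m in method])
    internal = pd.DataFrame(
        {
            "woman_id": census["woman_id"],
            "age_band": np.asarray(AGE_BANDS)[band],
            "empowerment_class": e,
            "need": need,
            "in_need": in_need,
            "modern": modern,
            "action_class": action_class,
            "infecund": infecund,
            "infecundity_rule": np.where(infecund, reason_idx + 1, 0),
        }
    )

    truth = _census_truth(spec, census, internal)
    if return_internal:
        return census, truth, internal
    return census, truth


def _share_by(groups: pd.Series, num_mask: np.ndarray, den_mask: np.ndarray) -> dict[str, float]:
    out = {}
    for level, idx in groups.groupby(groups).groups.items():
        den = den_mask[idx].sum()
        out[str(level)] = float(num_mask[idx].sum() / den) if den else float("nan")
    return out


def _census_truth(spec: PopulationSpec, census: pd.DataFrame, internal: pd.DataFrame) -> CensusTruth:
    modern = internal["modern"].to_numpy()
    in_need = internal["in_need"].to_numpy()
    method = census["current_method"].to_numpy()
    n = len(census)

    dfps = float(modern.sum() / in_need.sum())
    n_modern = modern.sum()
    class_shares = {
        c: float(((internal["action_class"] == c) & modern).sum() / n_modern)
        for c in ("SARC", "LARC", "PERMANENT")
    }
    method_shares = {
        m: float(((method == m) & modern).sum() / n_modern)
        for m in METHOD_CHOICES
        if m not in ("none", "traditional")
    }

    dfps_by: dict[str, dict[str, float]] = {}
    strats = {
        "age_band": internal["age_band"],
        "education_level": census["education_level"],
        "wealth_quintile": census["wealth_quintile"],
        "region_code": census["region_code"],
    }
    # SWPER categories scored on the census itself (complete cases)
    sw = swper_mod.swper_table(census)
    for d in swper_mod.DOMAINS:
        strats[f"swper_cat_{d}"] = sw[f"swper_cat_{d}"].fillna("incomplete")
    for name, groups in strats.items():
        dfps_by[name] = _share_by(groups, modern, in_need)

    perm = (internal["action_class"] == "PERMANENT").to_numpy() & modern
    sarc = (internal["action_class"] == "SARC").to_numpy() & modern
    permanent_share_by_age = _share_by(internal["age_band"], perm, modern)
    sarc_share_by_wealth = _share_by(census["wealth_quintile"], sarc, modern)

    fs = method == "female_sterilization"
    ster_truth: dict[str, Any] = {}
    if fs.any():
        sa = census.loc[fs, "ster_age"].to_numpy()
        sp = census.loc[fs, "ster_parity"].to_numpy()
        bands = np.select([sa < 25, sa < 30, sa < 35], ["<25", "25-29", "30-34"], ">=35")
        pbands = np.select([sp <= 1, sp == 2, sp == 3], ["0-1", "2", "3"], "4+")
        ster_truth["age_band_shares"] = {
            b: float((bands == b).mean()) for b in ("<25", "25-29", "30-34", ">=35")
        }
        ster_truth["parity_band_shares"] = {
            b: float((pbands == b).mean()) for b in ("0-1", "2", "3", "4+")
        }
        ster_truth["not_told_share"] = float(
            (~census.loc[fs, "ster_told_no_more"].astype(bool)).mean()
        )
        ster_truth["compensated_share"] = float(
            census.loc[fs, "ster_received_compensation"].astype(bool).mean()
        )
        ster_truth["regret_share"] = float(census.loc[fs, "ster_regrets"].astype(bool).mean())
        amounts = census.loc[fs, "ster_compensation_amount"]
        qs = census.loc[fs, "wealth_quintile"]
        ster_truth["mean_compensation_by_wealth"] = {
            str(qq): float(amounts[qs == qq].dropna().mean()) for qq in sorted(qs.unique())
        }
    return CensusTruth(
        n_women=n,
        dfps=dfps,
        class_shares=class_shares,
        method_shares=method_shares,
        dfps_by=dfps_by,
        permanent_share_by_age=permanent_share_by_age,
        sarc_share_by_wealth=sarc_share_by_wealth,
        sterilization=ster_truth,
    )


# ---------------------------------------------------------------------------
# closed-form population values
# ---------------------------------------------------------------------------


def expected_truth(spec: PopulationSpec) -> dict[str, Any]:
    """Analytically implied population DFPS and class shares.

    Enumerates the discrete covariate cells (region x age band x wealth
    x education x empowerment class) and mixes the method-choice and
    reproductive-state models in closed form.  Used as the
    law-of-large-numbers oracle for the generator.
    """
    spec.validate()
    n_bands = len(AGE_BANDS)
    p_modern_tot = 0.0
    p_need_tot = 0.0
    p_class = {c: 0.0 for c in ("SARC", "LARC", "PERMANENT")}

    strata = np.arange(spec.n_strata)
    wq = _wealth_probs(spec, strata)  # (n_strata, 5)
    edu = np.asarray(spec.education_given_wealth)  # (5, 3)
    emp = np.asarray(spec.empowerment_given_education)  # (3, 3)
    band_p = np.asarray(spec.age_band_probs)
    want_inneed = spec.wantedness_probs[1] + spec.wantedness_probs[2]
    pref = np.asarray(spec.preference_probs_by_band)
    pref_inneed = pref[:, 1:].sum(axis=1)  # after2y + no_more + unsure

    for s in strata:
        for a in range(n_bands):
            for qi in range(5):
                for edi in range(3):
                    for ei in range(3):
                        cell = (
                            (1.0 / spec.n_strata)
                            * band_p[a]
                            * wq[s, qi]
                            * edu[qi, edi]
                            * emp[edi, ei]
                        )
                        if cell == 0:
                            continue
                        probs = _method_probs(
                            spec,
                            np.array([a]),
                            np.array([edi]),
                            np.array([qi]),
                            np.array([ei]),
                        )[0]
                        p_by = dict(zip(METHOD_CHOICES, probs))
                        p_modern = sum(
                            v for m, v in p_by.items() if m not in ("none", "traditional")
                        )
                        p_none = p_by["none"]
                        fec = 1.0 - spec.infecund_prob_by_band[a]
                        p_preg = spec.pregnant_prob_by_band[a]
                        p_ppa = spec.ppa_prob_by_band[a]
                        p_nonuser_need = fec * (
                            p_preg * want_inneed
                            + (1 - p_preg)
                            * (p_ppa * want_inneed + (1 - p_ppa) * pref_inneed[a])
                        )
                        p_need = p_modern + p_by["traditional"] + p_none * p_nonuser_need
                        p_modern_tot += cell * p_modern
                        p_need_tot += cell * p_need
                        for m, v in p_by.items():
                            c = _CLASS_OF.get(m)
                            if c:
                                p_class[c] += cell * v

    return {
        "dfps": p_modern_tot / p_need_tot,
        "p_modern": p_modern_tot,
        "p_in_need": p_need_tot,
        "class_shares": {c: v / p_modern_tot for c, v in p_class.items()},
    }


# ---------------------------------------------------------------------------
# survey draw
# ---------------------------------------------------------------------------


def draw_survey(
    census: pd.DataFrame, design: DesignParams, seed: int
) -> pd.DataFrame:
    """Two-stage draw from a census frame: PPS PSUs within strata, then a
    systematic take of households within each selected PSU.

    Weights are inverse approximate inclusion probabilities
    (Hajek-style: the first-stage probability is approximated by
    n_h * size / total size, consistent with the with-replacement
    variance estimator downstream), optionally normalized to the sample
    size.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    psu_size = (
        census.groupby(["stratum_id", "psu_id"], sort=True)["household_id"]
        .nunique()
        .rename("n_households")
        .reset_index()
    )
    parts = []
    for stratum, g in psu_size.groupby("stratum_id", sort=True):
        if design.n_psus_per_stratum > len(g):
            raise ValueError(
                f"stratum {stratum}: requested {design.n_psus_per_stratum} PSUs, "
                f"only {len(g)} available"
            )
        sizes = g["n_households"].to_numpy(dtype=float)
        p = sizes / sizes.sum()
        sel = rng.choice(len(g), size=design.n_psus_per_stratum, replace=False, p=p)
        pi1 = np.minimum(design.n_psus_per_stratum * p[sel], 1.0)
        parts.append(
            pd.DataFrame(
                {
                    "psu_id": g["psu_id"].to_numpy()[sel],
                    "pi1": pi1,
                    "n_households": sizes[sel].astype(int),
                }
            )
        )
    selected = pd.concat(parts, ignore_index=True)

    psu_rows = census.groupby("psu_id", sort=True).indices
    hh_codes_all = census["household_id"].to_numpy()
    take_rows: list[np.ndarray] = []
    take_w: list[np.ndarray] = []
    for psu, pi1, n_hh in selected.itertuples(index=False):
        idx = psu_rows[psu]
        hh_codes = hh_codes_all[idx]
        hh = np.unique(hh_codes)
        take = min(design.households_per_psu, len(hh))
        # systematic selection with a random start
        start = rng.random()
        pick = np.unique(
            (np.floor((start + np.arange(take)) * len(hh) / take)).astype(int) % len(hh)
        )
        while len(pick) < take:  # guard against rounding collisions
            pick = np.unique(np.append(pick, rng.integers(0, len(hh))))
        chosen = hh[pick[:take]]
        pi2 = take / len(hh)
        mask = np.isin(hh_codes, chosen)
        take_rows.append(idx[mask])
        take_w.append(np.full(int(mask.sum()), 1.0 / (pi1 * pi2)))
    sample = census.iloc[np.concatenate(take_rows)].copy().reset_index(drop=True)
    sample["weight"] = np.concatenate(take_w)
    if design.normalize_weights:
        sample["weight"] *= len(sample) / sample["weight"].sum()
    return sample


# ---------------------------------------------------------------------------
# replicate recovery study
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Bias / RMSE / CI-coverage of the pipeline over replicate draws."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    truth: CensusTruth


def replicate_study(
    spec: PopulationSpec,
    design: DesignParams,
    n_reps: int,
    seed: int,
    census_seed: int | None = None,
) -> RecoveryReport:
    """Draw ``n_reps`` replicate surveys from one census and re-run the
    classification + estimation pipeline on each, comparing against the
    census truth.

    Tracks DFPS, the three class shares, and two stratified equity gaps
    (DFPS Q5 - Q1 in percentage points; DFPS secondary+ - no education).
    """
    from .fp_status import attach_status
    from .survey_estimation import SurveyDesign, weighted_proportion

    ss = np.random.SeedSequence(seed)
    if census_seed is None:
        census_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    census, truth = generate_census(spec, census_seed)

    sdesign = SurveyDesign()
    rep_seeds = [int(s % (2**31 - 1)) for s in np.random.SeedSequence(seed + 1).generate_state(n_reps)]
    quantities = {
        "dfps": truth.dfps,
        "share_SARC": truth.class_shares["SARC"],
        "share_LARC": truth.class_shares["LARC"],
        "share_PERMANENT": truth.class_shares["PERMANENT"],
        "gap_wealth_Q5_Q1_pp": truth.gap("wealth_quintile", "Q5", "Q1"),
        "gap_education_pp": truth.gap("education_level", "secondary_or_higher", "none"),
    }
    recs = []
    for r in range(n_reps):
        sample = draw_survey(census, design, rep_seeds[r])
        cls = attach_status(sample)
        dfps = weighted_proportion(
            cls, "in_dfps_numerator", "in_dfps_denominator", sdesign, "in_need", "dfps"
        )
        row: dict[str, Any] = {
            "rep": r,
            "n": len(sample),
            "dfps": dfps.p_hat,
            "dfps_ci_low": dfps.ci_low,
            "dfps_ci_high": dfps.ci_high,
            "dfps_covered": bool(dfps.ci_low <= truth.dfps <= dfps.ci_high),
        }
        modern = cls["in_dfps_numerator"].to_numpy()
        for c in ("SARC", "LARC", "PERMANENT"):
            est = weighted_proportion(
                cls, (cls["action_class"] == c).to_numpy(), modern, sdesign, "modern_users", c
            )
            row[f"share_{c}"] = est.p_hat
        in_den = cls["in_dfps_denominator"].to_numpy()
        wq = cls["wealth_quintile"]
        p_q5 = weighted_proportion(cls, "in_dfps_numerator", in_den & (wq == "Q5").to_numpy(), sdesign)
        p_q1 = weighted_proportion(cls, "in_dfps_numerator", in_den & (wq == "Q1").to_numpy(), sdesign)
        row["gap_wealth_Q5_Q1_pp"] = 100.0 * (p_q5.p_hat - p_q1.p_hat)
        edl = cls["education_level"]
        p_hi = weighted_proportion(
            cls, "in_dfps_numerator", in_den & (edl == "secondary_or_higher").to_numpy(), sdesign
        )
        p_no = weighted_proportion(cls, "in_dfps_numerator", in_den & (edl == "none").to_numpy(), sdesign)
        row["gap_education_pp"] = 100.0 * (p_hi.p_hat - p_no.p_hat)
        recs.append(row)
    per_rep = pd.DataFrame(recs)

    rows = []
    for qname, tval in quantities.items():
        est = per_rep[qname].to_numpy(dtype=float)
        row = {
            "quantity": qname,
            "truth": tval,
            "mean_estimate": float(est.mean()),
            "bias": float(est.mean() - tval),
            "rmse": float(np.sqrt(((est - tval) ** 2).mean())),
        }
        row["coverage"] = (
            float(per_rep["dfps_covered"].mean()) if qname == "dfps" else np.nan
        )
        rows.append(row)
    summary = pd.DataFrame(rows)
    return RecoveryReport(per_replicate=per_rep, summary=summary, truth=truth)
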