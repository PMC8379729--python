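# Methods

## The indicator

`fpequity` computes **demand for family planning satisfied with modern
methods (DFPS)** for partnered women aged 15–49 in complex survey
microdata, together with the contraceptive **method mix** and its
stratification by age, education, household wealth, region and the
SWPER women's-empowerment index.

A woman is *in need* of contraception (the DFPS denominator) if she is

* currently using any contraceptive method (modern or traditional), or
* pregnant or postpartum amenorrheic from a pregnancy that was mistimed
  or unwanted, or
* fecund, a non-user, and wanting no child within the next two years
  (or unsure whether/when she wants one).

She counts in the numerator if she currently uses a **modern** method:
pill, condom, injectable, diaphragm, spermicidal agents, emergency
contraception, IUD, or female/male sterilization.  Modern methods are
grouped into SARC (short-acting reversible: pill, injectable, condom,
diaphragm, spermicide, emergency), LARC (long-acting reversible: IUD
only) and PERMANENT (female and male sterilization).

A non-user is **infecund** if any of four rules fires (the
lowest-numbered firing rule is recorded): (1) married five or more
years with no contraceptive use and no pregnancy in that period,
(2) self-reported inability to get pregnant, (3) menopause,
hysterectomy or never having menstruated, (4) last menstrual period
more than six months ago while not postpartum amenorrheic.  A pregnant
woman is always treated as fecund.

Conventions that the indicator definition leaves open, pinned here:

* **Current users bypass the fecundity rules** and always sit in the
  denominator.  Rule 1 conditions explicitly on non-use, and sterilized
  or amenorrheic users must count as met need for the indicator to be
  well defined (the standard "demand satisfied" convention).
* **Traditional-method users** are met-need but not numerator members.
* **Pregnancy takes precedence over a reported method** (contraceptive
  failure edge): the wantedness of the pregnancy defines need.
* A pregnant non-user whose pregnancy was wanted then is *no need*.
* The residual "other modern" category (implants, patches) is modern;
  whether it counts as SARC or LARC is a configuration switch
  (`other_modern_class`, default SARC) because the category carries no
  sub-code.
* **Missing data** never classify silently: records whose need cannot
  be determined are excluded with a reason code
  (`fecundity_indeterminate`, `wantedness_missing`,
  `preference_missing`) and surface in QC output.  For sensitivity
  runs, `missing_preference="no_need"` treats a missing fertility
  preference as no need.

## SWPER scoring

The SWPER global index scores three empowerment domains — attitude to
violence (5 items), social independence (6 items), decision-making (3
items) — as linear combinations of all 14 recoded items plus a
per-domain intercept, standardized and cut into low/medium/high.  The
engine is strictly data-driven: recode tables, the 3×14 loading
matrix, intercepts, standardization constants and cutpoints live in a
versioned YAML config.  The packaged default
(`data/swper_global_synthetic.yaml`) is a **synthetic stand-in**: it has
the documented structure and realistic magnitudes (dominant own-domain
loadings, small cross-loadings) but is not a transcription of the
published coefficient tables; supply your own config file to score with
a specific published version.  Conventions: half-open category
intervals (a score exactly at a cutpoint takes the higher category); a
domain's score is missing when any of its own items is missing, while
missing *cross-domain* items fall back to reference means (their
weights are small).

## Survey estimation

All estimates are ratio estimators with sampling weights, with
Taylor-linearized variances under the ultimate-cluster
(with-replacement first stage) approximation; no finite-population
correction.  Domain estimation zero-weights out-of-domain records
rather than subsetting, so subpopulation SEs reflect the clustering of
domain members across all PSUs.  Degrees of freedom are #PSUs −
#strata over strata containing domain members.  Confidence intervals
are Wald intervals on the logit scale, back-transformed (respects
[0, 1]); degenerate estimates yield degenerate intervals.  Strata left
with a single PSU are collapsed into the neighbouring stratum in sorted
order (policy `collapse`; `error` raises instead).  The variance recipe
is pinned by a test against a Rao–Wu rescaled PSU bootstrap, since the
source analyses name their software but not their variance method;
matching any particular published CI to the last digit is therefore not
promised.

## Synthetic population

The generator (`synthetic_data`) emulates a national family-health
survey frame: strata = regions, PSUs drawn with probability
proportional to size (number of households), a systematic take of 22
households per sampled PSU, and all eligible women per household
(1–2).  Defaults: 8 strata × 400 PSUs × 40–80 households — a census of
roughly 240,000 women, of which a default draw samples ~5,000 (23 PSUs
per stratum), keeping the first-stage sampling fraction small so the
with-replacement variance approximation is appropriate, as it is for
the real survey the design mimics.

Covariates are deliberately discrete — region → wealth quintile →
education → a 3-level latent empowerment class — so that the population
DFPS and class shares have a closed form (`expected_truth`), used as a
law-of-large-numbers oracle.  Method choice is a multinomial logit in
age band, education, wealth and empowerment class whose intercepts are
calibrated once so the census shows DFPS ≈ 0.72 with a permanent share
among users ≈ 0.76, SARC ≈ 0.21 and LARC ≈ 0.03, a permanent share
rising with age and SARC rising with wealth, education and empowerment
— the structural patterns the reports should recover.  These are
calibration targets for the synthetic world, not claims about any real
survey.  Non-user reproductive states (infecundity rule, pregnancy,
amenorrhea, wantedness, fertility preference) are drawn from age-band
tables and the raw questionnaire fields are back-filled so the
classifier recovers the drawn state exactly (asserted in tests).
Sterilization details follow the published profile magnitudes:
age-at-sterilization ~ Normal(25.8, 4.5) truncated at the current age
(≈ 42% before 25), parity bands (3.3 / 43.4 / 29.4 / 23.9%), 20.8% not
told the procedure was permanent, compensation probability declining
from 76% (Q1) to 41% (Q5) with mean amounts rising from ≈ ₹660 to
≈ ₹785, and regret declining with parity at sterilization.

What the generator does *not* emulate: spatial correlation between
regions beyond the wealth tilt, household rosters beyond eligible
women, non-response beyond a small item-missingness knob (default 1%,
6% for age at first birth), and any real survey's weight
post-stratification.  Passing recovery tests therefore show that the
pipeline is design-consistent for this class of populations, not that
it reproduces any specific country's published estimates, which require
the original microdata.

## Problem sizes and numerical choices

The test suite and acceptance script use a ~240k-woman census, 300
replicate draws of ~5,000 women for bias/coverage, a ~1M-woman census
for the closed-form cross-check, and 10,000 bootstrap replicates for
the variance cross-check — sizes chosen so each check has comfortable
Monte-Carlo resolution relative to its tolerance.  All randomness flows
from explicit `numpy` `SeedSequence`s; census generation and survey
draws consume independent seeds so one census supports many replicate
draws; no global random state is used.  Share tables renormalize
nothing: partition identities (shares summing to 1, methods summing to
classes) hold to ~1e-9 by construction of the common denominator.
Output CSVs use fixed column order and `%.8g` float formatting so
re-runs are byte-identical.

## Known limitations

* The packaged SWPER constants are a synthetic stand-in (above);
  absolute score values are not comparable to published SWPER analyses
  until a transcribed config is supplied.
* First-stage PPS inclusion probabilities are Hájek-style
  approximations (`n_h · size / Σ size`, capped at 1); exact joint
  inclusion probabilities are out of scope since the variance estimator
  assumes with-replacement sampling anyway.
* Unmet need is not split into spacing vs limiting; no regression
  modelling, small-area estimation or multiple-testing adjustment.
* The sterilization profile restricts regret and told-permanent
  denominators to women with female sterilization; vasectomy regret is
  not separable in the emulated table.
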