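# Packaged default column dictionary.
#
# Maps plausible DHS-style recode variable names and numeric category
# codes onto the canonical schema.  Real deployments should supply their
# own dictionary file matching their export; canonical column names pass
# through untouched, so a file already in canonical form needs no
# dictionary at all.
columns:
  caseid: woman_id
  v021: psu_id
  v022: stratum_id
  v002: household_id
  v005: weight
  v012: age_years
  v502: in_union
  v106: education_level
  v190: wealth_quintile
  v024: region_code
  v213: currently_pregnant
  v225: pregnancy_wantedness
  v602: fertility_preference
  v312: current_method
  v215: months_since_last_period
  v405: postpartum_amenorrheic
  v512: years_in_union
category_note: >
  Category tables below translate numeric codes; codes already equal to
  canonical labels are passed through unchanged.
categories:
  current_method:
    "0": none
    "1": pill
    "2": iud
    "3": injectable
    "5": condom
    "6": female_sterilization
    "7": male_sterilization
    "8": traditional
    "9": traditional
    "10": traditional
    "14": diaphragm
    "15": spermicide
    "16": emergency
    "17": other_modern
  education_level:
    "0": none
    "1": primary
    "2": secondary_or_higher
    "3": secondary_or_higher
  wealth_quintile:
    "1": Q1
    "2": Q2
    "3": Q3
    "4": Q4
    "5": Q5
  pregnancy_wantedness:
    "1": wanted_then
    "2": wanted_later
    "3": wanted_not_at_all
  fertility_preference:
    "1": wants_within_2y
    "2": wants_after_2y
    "3": unsure
    "5": wants_no_more
period_special_codes:
  "994": menopause
  "995": before_last_birth
  "996": never_menstruated
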