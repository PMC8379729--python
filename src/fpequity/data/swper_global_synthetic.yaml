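# SWPER global scoring constants -- SYNTHETIC STAND-IN.
#
# This file has the documented structure of the published global SWPER
# scoring (14 items; a 3 x 14 loading matrix with dominant own-domain
# weights and small cross-weights; per-domain intercept, standardization
# constants and low/medium/high cutpoints), but the numeric values are a
# constructed stand-in, not a transcription of the published tables.
# The scoring engine treats this file as data: drop in a config with the
# published constants to score against a specific transcription.
#
# Recode conventions:
#   attitude-to-violence items: justified = -1, don't know = 0,
#     not justified = +1 (higher = more gender-equitable)
#   frequency of reading:      not at all = 0, < weekly = 1, weekly+ = 2
#   decision items:            husband/other alone = -1, joint = 0,
#     respondent alone = +1
#   numeric items pass through (years, ages, differences woman - husband).
version: synthetic-0.3
items:
  - att_beat_goes_out
  - att_beat_neglects_children
  - att_beat_argues
  - att_beat_refuses_sex
  - att_beat_burns_food
  - freq_reading
  - education_years
  - age_first_cohabitation
  - age_first_birth
  - age_difference
  - education_difference
  - decide_health
  - decide_purchases
  - decide_visits
recode:
  att_beat_goes_out: {justified: -1, dont_know: 0, not_justified: 1}
  att_beat_neglects_children: {justified: -1, dont_know: 0, not_justified: 1}
  att_beat_argues: {justified: -1, dont_know: 0, not_justified: 1}
  att_beat_refuses_sex: {justified: -1, dont_know: 0, not_justified: 1}
  att_beat_burns_food: {justified: -1, dont_know: 0, not_justified: 1}
  freq_reading: {not_at_all: 0, less_than_weekly: 1, weekly: 2}
  decide_health: {husband_or_other: -1, joint: 0, respondent_alone: 1}
  decide_purchases: {husband_or_other: -1, joint: 0, respondent_alone: 1}
  decide_visits: {husband_or_other: -1, joint: 0, respondent_alone: 1}
weights:
  # attitude to violence
  - [0.508, 0.508, 0.526, 0.538, 0.588, 0.083, 0.009, 0.004, 0.004, 0.001, 0.004, 0.011, 0.004, 0.015]
  # social independence
  - [0.012, 0.026, 0.014, 0.009, 0.028, 0.422, 0.081, 0.133, 0.139, 0.031, 0.054, 0.007, 0.019, 0.025]
  # decision making
  - [0.001, 0.030, 0.002, 0.009, 0.011, 0.065, 0.009, 0.006, 0.012, 0.008, 0.010, 0.770, 0.831, 0.768]
intercepts: [-0.138, -6.210, -0.133]
# standardization: (raw - center) / scale, constructed so scores are
# approximately mean 0, sd 1 in the reference population
centers: [0.546, -0.012, -0.157]
scales: [1.699, 1.367, 1.436]
cutpoints:
  - [-0.700, 0.400]   # attitude to violence
  - [-0.559, 0.293]   # social independence
  - [-1.000, 0.600]   # decision making
# per-domain support: a domain's score is missing when any of these
# items is missing; missing off-support items use reference_means
domain_items:
  - [0, 1, 2, 3, 4]
  - [5, 6, 7, 8, 9, 10]
  - [11, 12, 13]
reference_means: [0.55, 0.55, 0.55, 0.55, 0.55, 0.8, 6.3, 20.0, 22.0, -4.5, -2.0, 0.2, 0.2, 0.2]
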