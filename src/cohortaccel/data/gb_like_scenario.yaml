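# Default multistage simulation scenario: qualitatively GB-male-like.
# 17 cohorts 1895-99 .. 1975-79 observed over registry years 1975-2014;
# the number of rate-limiting steps k falls from 7 to 5 across cohorts
# (true acceleration 6 -> 4) while incidence at age 60 rises from 6 to 44
# per 100,000 person-years.
first_cohort: 1895
last_cohort: 1975
min_age: 25
years: [1975, 2014]
k_anchors:
  1895: 7.0
  1975: 5.0
rate60_anchors:
  1895: 6.0
  1975: 44.0
person_years: 3.0e+6
seed: 0
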