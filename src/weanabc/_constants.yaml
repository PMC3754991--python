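# Physiological constants behind the subadult bone-turnover model.
#
# The tissue-level model has three ingredients:
#   1. a bone-mineral mass growth curve M(x) (sum of three logistic
#      components, grams of skeletal mineral vs age in years), anchored to
#      reference skeletal-calcium values for a growing individual
#      (~28 g at birth, ~100 g at 1 y, ~220 g at 5 y, ~400 g at 10 y,
#      ~800 g at 15 y, plateau ~1.1 kg in the early twenties);
#   2. an age-dependent trabecular remodeling rate R(x) (fraction of
#      existing bone replaced per year, log-quartic in age), high in
#      infancy (~0.5/yr) and declining toward the adult cancellous-bone
#      range (~0.1/yr) by the late teens;
#   3. a mineralization law m(lag): the cumulative fraction of a collagen
#      cohort's full mineral load acquired by `lag` whole years after the
#      matrix was formed.  Primary mineralization is fast (>70% within
#      days); the secondary remainder accrues over years and is modelled
#      with two exponential components.
#
# Constants were calibrated jointly, within the plausible ranges of the
# cited tissue-level literature, against published estimates of cancellous
# bone mineral and collagen turnover in subadults.  Revise here, not in
# code.

mineral_mass:
  # M(x) = sum_i amplitude_i / (1 + exp(-rate_i * (x - midpoint_i)))
  components:
    - {amplitude: 571.769891, rate: 0.652578717, midpoint: -1.26952748}
    - {amplitude: -372.925169, rate: -0.496991770, midpoint: 16.0586896}
    - {amplitude: 574.698388, rate: 0.448742682, midpoint: 11.6242144}

remodeling:
  # R(x) = exp(q0 + q1*x + q2*x^2 + q3*x^3 + q4*x^4), fraction per year
  log_coefficients: [-0.790984918, 0.250292709, -0.0647049287,
                     0.00453231037, -0.000107157584]

mineralization_law:
  # m(lag) = 1 - (1-primary)*(split*slow1^lag + (1-split)*slow2^lag)
  primary_fraction: 0.8246756054499977   # mineral acquired in the formation year
  secondary_split: 0.5058202782461579    # weight of the faster secondary phase
  secondary_retention_fast: 0.7272391359193323  # per-year retention, fast phase
  secondary_retention_slow: 0.9932846881904602  # per-year retention, slow phase
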