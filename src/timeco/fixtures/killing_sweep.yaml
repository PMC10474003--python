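# Bifurcation diagrams over the conversion rate, for several ATI killing
# rates.  alpha_TA and omega are swept; the scalars below are
# representative values (alpha_TA in the regime where the tumor cannot
# invade the cancer-free state, omega at the left end of its interval).
parameters:
  r_T: 1.0
  K_T: 1.0
  d_P: 1.0
  r_A: 1.0
  K_A: 1.0
  alpha_TP: 0.95
  alpha_TA: 1.5
  alpha_PT: 0.15
  alpha_AT: 0.05
  alpha_AP: 0.5
  omega: 0.0
seed: 0
options:
  ranges:
    alpha_TA: [0.0, 2.0]
    omega: [0.0, 2.0]
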