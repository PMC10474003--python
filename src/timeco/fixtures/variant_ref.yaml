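# Variant comparison (all eight structural variants); omega is swept.
# alpha_PT takes the values 0 or 0.15 across variants: the zero case
# corresponds to the variants with the PTI tumor-growth switch off, which
# remove the alpha_PT term structurally, so the scalar here is 0.15.
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
    omega: [0.0, 5.0]
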