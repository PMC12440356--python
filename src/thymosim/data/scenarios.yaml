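reference: {}
s6:
  n_subdivisions: 2
  n_protrusions: 3
  tec_radius: 2.0
s2:
  n_subdivisions: 2
  n_protrusions: 3
  tec_radius: 2.5
s3:
  n_subdivisions: 2
  n_protrusions: 3
  tec_radius: 3.0
s4:
  n_subdivisions: 2
  n_protrusions: 4
  tec_radius: 2.0
s5:
  n_subdivisions: 2
  n_protrusions: 4
  tec_radius: 2.5
s7:
  n_subdivisions: 2
  n_protrusions: 4
  tec_radius: 3.0
s8:
  n_subdivisions: 2
  n_protrusions: 5
  tec_radius: 2.0
s9:
  n_subdivisions: 2
  n_protrusions: 5
  tec_radius: 2.5
s10:
  n_subdivisions: 2
  n_protrusions: 5
  tec_radius: 3.0
s11:
  n_subdivisions: 3
  n_protrusions: 3
  tec_radius: 2.0
s12:
  n_subdivisions: 3
  n_protrusions: 3
  tec_radius: 2.5
s13:
  n_subdivisions: 3
  n_protrusions: 3
  tec_radius: 3.0
s1:
  n_subdivisions: 3
  n_protrusions: 4
  tec_radius: 2.0
s14:
  n_subdivisions: 3
  n_protrusions: 4
  tec_radius: 3.0
s15:
  n_subdivisions: 3
  n_protrusions: 5
  tec_radius: 2.0
s16:
  n_subdivisions: 3
  n_protrusions: 5
  tec_radius: 2.5
s17:
  n_subdivisions: 3
  n_protrusions: 5
  tec_radius: 3.0
s18:
  n_subdivisions: 4
  n_protrusions: 3
  tec_radius: 2.0
s19:
  n_subdivisions: 4
  n_protrusions: 3
  tec_radius: 2.5
s20:
  n_subdivisions: 4
  n_protrusions: 3
  tec_radius: 3.0
s21:
  n_subdivisions: 4
  n_protrusions: 4
  tec_radius: 2.0
s22:
  n_subdivisions: 4
  n_protrusions: 4
  tec_radius: 2.5
s23:
  n_subdivisions: 4
  n_protrusions: 4
  tec_radius: 3.0
s24:
  n_subdivisions: 4
  n_protrusions: 5
  tec_radius: 2.0
s25:
  n_subdivisions: 4
  n_protrusions: 5
  tec_radius: 2.5
s26:
  n_subdivisions: 4
  n_protrusions: 5
  tec_radius: 3.0
s27:
  il7_expression_mode: all_tecs
s28:
  il7_expression_mode: none
s29:
  depletion: false
  il7_deactivation_rate: 100.0
  il7_activation_rate: 120.0
s36:
  depletion: true
  il7_deactivation_rate: 50.0
  il7_activation_rate: 240.0
s44:
  depletion: true
  il7_deactivation_rate: 25.0
  il7_activation_rate: 480.0
s45:
  depletion: false
  il7_deactivation_rate: 25.0
  il7_activation_rate: 480.0
lesion-il7r-wt:
  lesion:
    kinds:
    - IL7R_WT
lesion-il7r-da:
  lesion:
    kinds:
    - IL7R_DA
lesion-il7r-hi:
  lesion:
    kinds:
    - IL7R_HI
lesion-il7-autocrine:
  lesion:
    kinds:
    - IL7_AUTOCRINE
lesion-notch1-da:
  lesion:
    kinds:
    - NOTCH1_DA
lesion-delayed-diff:
  lesion:
    kinds:
    - DELAYED_DIFF
lesion-slow-speed:
  lesion:
    kinds:
    - SLOW_SPEED
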