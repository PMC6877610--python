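# Stage c: activation voltage dependence retuned (alpha_m shifted/steepened,
# beta_h moved to depolarized range) for the current-voltage curves.
name: nav15_hh_row_c
family: hh
gbar: 0.1
E_rev: 65.0
temperature:
  T: 24.0
  T_base: 6.3
  q10_base: 3.0
gates:
- name: m
  exponent: 3
  alpha:
    form: linoid
    params:
      A: 0.02
      V_half: -48
      k: 6
  beta:
    form: exponential
    params:
      A: 0.2
      V_half: -60
      k: -100
- name: h
  exponent: 1
  alpha:
    form: exponential
    params:
      A: 0.002
      V_half: -65
      k: -10
  beta:
    form: sigmoid
    params:
      A: 1.2
      V_half: 20
      k: -23
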