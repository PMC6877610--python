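# Trade-off alpha_h (between availability- and repriming-optimized
# settings) with the m3h conductance, for fast-inactivation protocols.
name: nav15_hh_variant_c
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
      A: 0.015
      V_half: -54
      k: 6
  beta:
    form: exponential
    params:
      A: 0.4
      V_half: -70
      k: -35
- name: h
  exponent: 1
  alpha:
    form: exponential
    params:
      A: 0.004
      V_half: -75
      k: -16
  beta:
    form: sigmoid
    params:
      A: 0.9
      V_half: 20
      k: -25
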