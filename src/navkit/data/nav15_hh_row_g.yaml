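# Stage g: slow-inactivation gate s added (m3*h*s); alpha_h holds the
# trade-off ('variant c') values.
name: nav15_hh_row_g
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
- name: s
  exponent: 1
  alpha:
    form: exponential
    params:
      A: 9.2e-05
      V_half: -65
      k: -55
  beta:
    form: sigmoid
    params:
      A: 0.00011
      V_half: -20
      k: -10
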