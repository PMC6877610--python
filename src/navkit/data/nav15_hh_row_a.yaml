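# Stage a: the original squid-axon HH sodium channel rate parameters,
# rewritten in the modern (A, V1/2, k) convention, run as a NaV1.5 baseline.
name: nav15_hh_row_a
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
      A: 0.1
      V_half: -40
      k: 10
  beta:
    form: exponential
    params:
      A: 4
      V_half: -65
      k: -18
- name: h
  exponent: 1
  alpha:
    form: exponential
    params:
      A: 0.07
      V_half: -65
      k: -20
  beta:
    form: sigmoid
    params:
      A: 1
      V_half: -35
      k: -10
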