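# Original Hodgkin-Huxley squid giant axon sodium channel, modern
# voltage convention (rest -65 mV), rates defined at 6.3 C.
name: hh_squid_original
family: hh
gbar: 0.12
E_rev: 50.0
temperature:
  T: 6.3
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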