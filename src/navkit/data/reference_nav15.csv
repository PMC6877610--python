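feature_id,description,exp_mean,exp_sd,units
activation_v_half,Half-maximal activation voltage of the normalized conductance-voltage Boltzmann,-34.5,1.5,mV
activation_k,Slope factor of the activation Boltzmann,-7.2,0.6,mV
availability_v_half,Half-maximal inactivation voltage of the steady-state availability curve,-89.1,1.6,mV
availability_k,Slope factor of the availability Boltzmann,5.5,0.4,mV
recovery_fast_tau_m120,Time constant of recovery from fast inactivation at -120 mV,5.1,0.9,ms
recovery_fast_tau_m110,Time constant of recovery from fast inactivation at -110 mV,12.5,2.1,ms
recovery_fast_tau_m100,Time constant of recovery from fast inactivation at -100 mV,26.1,3.8,ms
recovery_fast_tau_m90,Time constant of recovery from fast inactivation at -90 mV,47.9,3.4,ms
recovery_slow_tau1,First time constant of recovery from slow inactivation,5.1,0.9,ms
recovery_slow_frac1,Fractional recovery with the first time constant,78,,%
recovery_slow_tau2,Second time constant of recovery from slow inactivation,596.3,,ms
recovery_slow_frac2,Fractional recovery with the second time constant,22,,%
slow_onset_tau,Time constant of the development of slow inactivation,1.79,0.11,s
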