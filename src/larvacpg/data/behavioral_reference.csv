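quantity,condition,mean,sd,n_waves,n_animals
normalized_contraction_duration,forward_25C,0.415,0.076,35,12
intersegmental_phase_lag,forward_25C,0.087,0.050,35,12
wave_duration_s,forward_25C,1.39,0.25,35,12
duty_cycle,forward_25C,0.83,0.22,35,12
normalized_contraction_duration,forward_34C,,,15,10
normalized_contraction_duration,backward_34C,,,14,10
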