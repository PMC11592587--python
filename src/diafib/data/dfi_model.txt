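# Diabetes Fibrosis Index: published coefficients and screening cut-off.
name = dfi
theta_age = 1.4013
platelets_amplitude = -2.9859
platelets_curvature = 0.00159
ast_amplitude = 5.8155
ast_curvature = 0.00365
theta_alt = -1.2014
bmi_amplitude = 56.7468
bmi_curvature = 0.01467
cutoff = 715.0
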