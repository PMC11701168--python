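parameter,mean,ci_low,ci_high
beta0,1.71,0.77,2.54
beta_canada,0.12,-0.69,1.06
beta_age,-0.23,-0.26,-0.20
beta_dose,0.05,0.03,0.07
sigma_u_sq,0.93,0.48,1.99
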