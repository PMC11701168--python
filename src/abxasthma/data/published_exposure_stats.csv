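quantity,value
total_births_2001_2018,773160
total_prescriptions_2001_2018,404675
male_rate_per_1000,586
female_rate_per_1000,457
bc_rate_per_1000_2000,868
bc_rate_per_1000_2018,236
unit_cost_cad_2024,550
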