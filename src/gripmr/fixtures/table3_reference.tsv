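outcome	presentation	estimate	ci_lower	ci_upper	p_value
coronary_artery_disease	or	0.94	0.91	0.99	0.01
myocardial_infarction	or	0.93	0.89	0.98	0.003
type_2_diabetes	or	0.99	0.96	1.02	0.52
body_mass_index	beta	0.0003	-0.01	0.02	0.97
ldl_cholesterol	beta	-0.005	-0.01	0.001	0.11
hdl_cholesterol	beta	-0.002	-0.03	0.02	0.90
triglycerides	beta	-0.007	-0.03	0.01	0.49
fasting_glucose	beta	-0.003	-0.01	0.0006	0.09
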