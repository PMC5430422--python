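snp_id	effect_allele	other_allele	or	ci_lower	ci_upper	p_value	scale
rs3121278	T	G	1.02	0.98	1.05	0.39	SD-units
rs752045	G	A	0.98	0.96	1.01	0.19	SD-units
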