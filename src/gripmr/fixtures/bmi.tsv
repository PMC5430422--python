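snp_id	effect_allele	other_allele	or	ci_lower	ci_upper	p_value	scale
rs3121278	T	G	0.99	0.96	1.02	0.50	SD-units
rs752045	G	A	1.01	0.98	1.03	0.62	SD-units
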