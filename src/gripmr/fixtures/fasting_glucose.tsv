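snp_id	effect_allele	other_allele	or	ci_lower	ci_upper	p_value	scale
rs3121278	T	G	0.99	0.97	1.02	0.62	mmol/l
rs752045	G	A	1.00	0.98	1.02	0.92	mmol/l
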