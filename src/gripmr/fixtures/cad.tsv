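snp_id	effect_allele	other_allele	or	ci_lower	ci_upper	p_value	scale
rs3121278	T	G	0.93	0.85	1.02	0.12	log-odds
rs752045	G	A	0.95	0.9	0.9995	0.047	log-odds
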