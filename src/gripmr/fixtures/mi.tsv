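snp_id	effect_allele	other_allele	or	ci_lower	ci_upper	p_value	scale
rs3121278	T	G	0.90	0.81	0.99	0.03	log-odds
rs752045	G	A	0.94	0.89	0.99	0.03	log-odds
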