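snp_id	nearest_gene	beta	se	effect_allele	other_allele	p_value	eaf	n
rs3121278	BMS1L	-0.26	0.06	T	G	6.18e-5	0.18	34,910
rs752045	CSMD1	0.47	0.08	G	A	5.20e-10	0.18	34,910
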