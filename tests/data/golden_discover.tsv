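# rvburden v0.1.0 config=none
gene_id	best_class	odds_ratio	p_value	n_tests_gene	significant
GA	meta	66.12793733681463	8.246662166223677e-12	3	True
GD	meta	50.3904282115869	3.3770744096857444e-05	3	True
GC	class_I	10.137055837563452	0.012039762273022805	1	False
GB	class_II	2.0050251256281406	0.43591148173794675	1	False
GF	class_I	1.2564102564102564	0.5979647604882662	1	False
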