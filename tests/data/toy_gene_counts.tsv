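gene_id	case_class_I	control_class_I	case_class_II	control_class_II	case_synonymous	control_synonymous
GA	9	1	4	1	2	30
GB	0	2	1	5	2	30
GC	3	3	0	0	2	30
GD	2	0	3	1	1	28
GE	1	1	0	0	3	2
GF	5	40	0	0	2	30
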