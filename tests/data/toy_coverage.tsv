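gene_id	coverage_internal	coverage_external
GA	0.95	0.9
GB	0.9	0.88
GC	0.92	0.93
GD	0.99	0.97
GE	0.97	0.75
GF	0.91	0.89
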