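input_ng	ppv_tp	ppv_fp	lod95_snv_percent	specificity_tn	specificity_fp
30	249	9	1	72	5
40	300	8	1	96	7
50	252	7	0.5	72	6
60	249	4	0.5	72	6
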