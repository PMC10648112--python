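variant_type	input_ng	tier_vaf_percent	detected	total
SNV	30	0.125	17	45
SNV	30	0.25	29	45
SNV	30	0.5	41	45
SNV	30	1	45	45
SNV	30	2	44	45
SNV	40	0.125	20	60
SNV	40	0.25	35	45
SNV	40	0.5	70	75
SNV	40	1	45	45
SNV	40	2	45	45
SNV	50	0.125	16	45
SNV	50	0.25	33	45
SNV	50	0.5	43	45
SNV	50	1	45	45
SNV	50	2	45	45
SNV	60	0.125	15	45
SNV	60	0.25	31	45
SNV	60	0.5	42	45
SNV	60	1	45	45
SNV	60	2	45	45
INDEL	30	0.125	4	27
INDEL	30	0.25	10	27
INDEL	30	0.5	18	27
INDEL	30	1	20	27
INDEL	30	2	21	27
INDEL	40	0.125	7	36
INDEL	40	0.25	10	27
INDEL	40	0.5	21	45
INDEL	40	1	21	27
INDEL	40	2	21	27
INDEL	50	0.125	5	27
INDEL	50	0.25	9	27
INDEL	50	0.5	16	27
INDEL	50	1	19	27
INDEL	50	2	21	27
INDEL	60	0.125	5	27
INDEL	60	0.25	9	27
INDEL	60	0.5	16	27
INDEL	60	1	19	27
INDEL	60	2	21	27
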