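gene	chrom	pos	ref	alt	cdna_change	protein_change	homopolymer_base	homopolymer_run_len	context_start	synthetic_context_seq
APC	chr5	112175952	C	CA	4666_4667insA	T1556fs*3	A	6	112175902	TATTAGGCGCGTTATAGAGTTCGTGATAGGGTCTCCACTCAAGGAACTTTCAAAAAAGGGTAAGGGTGCCCTCGGGTCTTCGCGACACACTGCGGGCACCC
TP53	chr17	7579419	TC	T	263delC	S90fs*33	C	5	7579369	AACGCAGGATATAGTCCTATTACATCTCGACTTCGGCCGGCCGCAAACTATCCCCCTTAAAGAGTTCTACTGTAAACGGACGCGATTGATGTTTCTGTCAC
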