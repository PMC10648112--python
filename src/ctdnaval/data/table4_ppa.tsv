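pipeline	concordant	ortho_only
standard	40	8
ldt	44	4
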