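reference,non_atypical,gp3,gp4plus
non_atypical,93,5,2
gp3,14,73,13
gp4plus,7,17,77
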