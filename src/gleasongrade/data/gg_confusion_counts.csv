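reference,gg1,gg2,gg3,gg4
gg1,19,4,0,1
gg2,1,2,1,0
gg3,2,0,2,1
gg4,0,1,3,3
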