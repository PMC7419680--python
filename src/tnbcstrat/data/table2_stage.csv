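stage,TC0,TC1,TC2,TC3
early,3,2,9,3
locally_advanced,8,4,11,1
metastatic,2,1,1,3
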