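smoking,TC0,TC1,TC2,TC3
yes,7,4,6,3
no,8,3,15,4
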