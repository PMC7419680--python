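score,count
TC0,15
TC1,7
TC2,21
TC3,7
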