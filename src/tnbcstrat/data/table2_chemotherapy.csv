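chemotherapy,TC0,TC1,TC2,TC3
neoadjuvant,11,3,10,2
non_neoadjuvant,4,4,11,4
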