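population,temperature_c,female_id,eggs
temperate,15,1,3
temperate,15,2,7
temperate,15,3,11
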