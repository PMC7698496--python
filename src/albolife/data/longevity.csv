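population,temperature_c,mean_days,se_days,min_days,max_days,n
temperate,10,5.7,0.4,2,10,20
temperate,15,27.9,2.0,8,45,20
temperate,25,64.5,3.8,32,92,20
temperate,30,53.5,4.7,14,86,20
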