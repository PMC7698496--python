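population,temperature_c,cycle_index,n_females,duration_mean,duration_se,duration_min,eggs_mean,eggs_se
temperate,25,1,20,4.2,0.1,4,31.7,2.0
temperate,25,2,20,4.0,0.0,3,40.1,2.3
temperate,25,3,20,3.0,0.0,3,40.8,2.1
temperate,25,4,20,4.0,0.0,4,40.4,2.3
temperate,25,5,17,3.0,0.0,3,39.4,2.5
temperate,25,6,16,3.6,0.2,3,31.6,4.7
temperate,25,7,16,3.9,0.1,3,30.0,3.5
temperate,25,8,13,4.2,0.4,3,25.4,5.0
temperate,25,9,9,4.1,0.1,4,29.4,8.3
temperate,25,10,5,4.2,0.2,4,19.0,0.4
temperate,25,11,2,7.5,2.5,5,6.0,3.0
temperate,30,1,20,3.1,0.1,2,55.9,4.0
temperate,30,2,12,3.3,0.2,2,55.0,8.2
temperate,30,3,3,4.3,0.9,3,60.7,13.2
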