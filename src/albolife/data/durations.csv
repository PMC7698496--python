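population,temperature_c,stage_from,stage_to,mean_days,se_days,n
temperate,10,L1,L2,37.4,0.7,38
temperate,15,Egg,L1,2.0,0.1,2
temperate,15,L1,L2,5.8,0.1,98
temperate,15,L2,L3,5.1,0.2,97
temperate,15,L3,L4,7.0,0.1,97
temperate,15,L4,Pupa,16.7,0.4,95
temperate,15,Pupa,Adult,10.7,0.3,73
temperate,15,L1,Adult,36.8,0.5,73
temperate,25,Egg,L1,3.8,0.4,28
temperate,25,L1,L2,2.5,0.1,97
temperate,25,L2,L3,2.0,0.1,96
temperate,25,L3,L4,2.4,0.1,95
temperate,25,L4,Pupa,5.0,0.1,94
temperate,25,Pupa,Adult,3.5,0.1,81
temperate,25,L1,Adult,12.7,0.2,81
temperate,30,Egg,L1,3.2,0.3,53
temperate,30,L1,L2,2.0,0.0,97
temperate,30,L2,L3,1.1,0.0,96
temperate,30,L3,L4,1.4,0.1,94
temperate,30,L4,Pupa,3.5,0.1,85
temperate,30,Pupa,Adult,1.9,0.0,71
temperate,30,L1,Adult,7.6,0.1,71
subtropical,10,Egg,L1,2.0,0.0,4
subtropical,15,Egg,L1,7.4,1.8,9
subtropical,15,L1,L2,5.6,0.3,71
subtropical,15,L2,L3,3.3,0.2,66
subtropical,15,L3,L4,4.6,0.2,57
subtropical,15,L4,Pupa,13.4,0.8,48
subtropical,15,Pupa,Adult,8.7,0.6,40
subtropical,15,L1,Adult,35.0,0.9,40
subtropical,25,Egg,L1,4.5,0.7,64
subtropical,25,L1,L2,2.1,0.2,74
subtropical,25,L2,L3,1.2,0.2,70
subtropical,25,L3,L4,1.2,0.1,67
subtropical,25,L4,Pupa,3.3,0.2,65
subtropical,25,Pupa,Adult,2.7,0.1,61
subtropical,25,L1,Adult,10.4,0.7,61
subtropical,30,Egg,L1,6.7,0.7,71
subtropical,30,L1,L2,1.4,0.1,70
subtropical,30,L2,L3,1.3,0.1,69
subtropical,30,L3,L4,1.4,0.2,66
subtropical,30,L4,Pupa,3.0,0.3,60
subtropical,30,Pupa,Adult,1.9,0.1,54
subtropical,30,L1,Adult,8.8,0.6,54
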