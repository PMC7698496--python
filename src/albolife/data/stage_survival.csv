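population,temperature_c,stage_from,stage_to,trials,successes,printed_fraction,printed_se,status
temperate,10,Egg,L1,120,0,0.00,,observed
temperate,10,L1,L2,100,38,0.38,0.05,observed
temperate,10,L2,L3,38,0,0.00,,observed
temperate,10,L3,L4,0,0,,,not_run
temperate,10,L4,Pupa,0,0,,,not_run
temperate,10,Pupa,Adult,0,0,,,not_run
temperate,15,Egg,L1,120,2,0.02,0.01,observed
temperate,15,L1,L2,100,98,0.98,0.01,observed
temperate,15,L2,L3,98,97,0.99,0.01,observed
temperate,15,L3,L4,97,97,1.00,,observed
temperate,15,L4,Pupa,97,95,0.98,0.01,observed
temperate,15,Pupa,Adult,95,73,0.77,0.04,observed
temperate,25,Egg,L1,120,28,0.23,0.04,observed
temperate,25,L1,L2,100,97,0.97,0.02,observed
temperate,25,L2,L3,97,96,0.99,0.01,observed
temperate,25,L3,L4,96,95,0.99,0.01,observed
temperate,25,L4,Pupa,95,94,0.99,0.01,observed
temperate,25,Pupa,Adult,94,81,0.86,0.04,observed
temperate,30,Egg,L1,120,53,0.44,0.05,observed
temperate,30,L1,L2,100,97,0.97,0.02,observed
temperate,30,L2,L3,97,96,0.99,0.01,observed
temperate,30,L3,L4,96,94,0.98,0.01,observed
temperate,30,L4,Pupa,94,85,0.90,0.03,observed
temperate,30,Pupa,Adult,85,71,0.84,0.04,observed
subtropical,10,Egg,L1,100,4,0.04,0.02,observed
subtropical,10,L1,L2,80,0,0.00,,observed
subtropical,10,L2,L3,0,0,,,not_run
subtropical,10,L3,L4,0,0,,,not_run
subtropical,10,L4,Pupa,0,0,,,not_run
subtropical,10,Pupa,Adult,0,0,,,not_run
subtropical,15,Egg,L1,110,9,0.08,0.03,observed
subtropical,15,L1,L2,80,71,0.89,0.04,observed
subtropical,15,L2,L3,71,66,0.93,0.03,observed
subtropical,15,L3,L4,66,57,0.86,0.04,observed
subtropical,15,L4,Pupa,57,48,0.84,0.05,observed
subtropical,15,Pupa,Adult,48,40,0.83,0.05,observed
subtropical,25,Egg,L1,130,64,0.49,0.04,observed
subtropical,25,L1,L2,80,74,0.93,0.03,observed
subtropical,25,L2,L3,74,70,0.95,0.03,observed
subtropical,25,L3,L4,70,67,0.96,0.02,observed
subtropical,25,L4,Pupa,67,65,0.97,0.02,observed
subtropical,25,Pupa,Adult,65,61,0.94,0.03,observed
subtropical,30,Egg,L1,140,71,0.51,0.04,observed
subtropical,30,L1,L2,80,70,0.88,0.04,observed
subtropical,30,L2,L3,70,69,0.99,0.01,observed
subtropical,30,L3,L4,69,66,0.96,0.02,observed
subtropical,30,L4,Pupa,66,60,0.91,0.04,observed
subtropical,30,Pupa,Adult,60,54,0.90,0.04,observed
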