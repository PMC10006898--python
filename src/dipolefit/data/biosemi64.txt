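Fp1 -0.308829 +0.950477 -0.034899
AF7 -0.587427 +0.808524 -0.034899
AF3 -0.406247 +0.871199 +0.275637
F1 -0.286965 +0.710264 +0.642788
F3 -0.545007 +0.673028 +0.500000
F5 -0.728993 +0.633704 +0.258819
F7 -0.808524 +0.587427 -0.034899
FT7 -0.950477 +0.308829 -0.034899
FC5 -0.887888 +0.340828 +0.309017
FC3 -0.676377 +0.359636 +0.642788
FC1 -0.374710 +0.374710 +0.848048
C1 -0.390731 -0.000000 +0.920505
C3 -0.719340 -0.000000 +0.694658
C5 -0.933580 -0.000000 +0.358368
T7 -0.999391 -0.000000 -0.034899
TP7 -0.950477 -0.308829 -0.034899
CP5 -0.887888 -0.340828 +0.309017
CP3 -0.676377 -0.359636 +0.642788
CP1 -0.374710 -0.374710 +0.848048
P1 -0.286965 -0.710264 +0.642788
P3 -0.545007 -0.673028 +0.500000
P5 -0.728993 -0.633704 +0.258819
P7 -0.808524 -0.587427 -0.034899
P9 -0.733218 -0.532714 -0.422618
PO7 -0.587427 -0.808524 -0.034899
PO3 -0.406247 -0.871199 +0.275637
O1 -0.308829 -0.950477 -0.034899
Iz +0.000000 -0.906308 -0.422618
Oz +0.000000 -0.999391 -0.034899
POz +0.000000 -0.933580 +0.358368
Pz +0.000000 -0.719340 +0.694658
CPz +0.000000 -0.390731 +0.920505
Fpz +0.000000 +0.999391 -0.034899
Fp2 +0.308829 +0.950477 -0.034899
AF8 +0.587427 +0.808524 -0.034899
AF4 +0.406247 +0.871199 +0.275637
AFz +0.000000 +0.933580 +0.358368
Fz +0.000000 +0.719340 +0.694658
F2 +0.286965 +0.710264 +0.642788
F4 +0.545007 +0.673028 +0.500000
F6 +0.728993 +0.633704 +0.258819
F8 +0.808524 +0.587427 -0.034899
FT8 +0.950477 +0.308829 -0.034899
FC6 +0.887888 +0.340828 +0.309017
FC4 +0.676377 +0.359636 +0.642788
FC2 +0.374710 +0.374710 +0.848048
FCz +0.000000 +0.390731 +0.920505
Cz +0.000000 +0.000000 +1.000000
C2 +0.390731 +0.000000 +0.920505
C4 +0.719340 +0.000000 +0.694658
C6 +0.933580 +0.000000 +0.358368
T8 +0.999391 +0.000000 -0.034899
TP8 +0.950477 -0.308829 -0.034899
CP6 +0.887888 -0.340828 +0.309017
CP4 +0.676377 -0.359636 +0.642788
CP2 +0.374710 -0.374710 +0.848048
P2 +0.286965 -0.710264 +0.642788
P4 +0.545007 -0.673028 +0.500000
P6 +0.728993 -0.633704 +0.258819
P8 +0.808524 -0.587427 -0.034899
P10 +0.733218 -0.532714 -0.422618
PO8 +0.587427 -0.808524 -0.034899
PO4 +0.406247 -0.871199 +0.275637
O2 +0.308829 -0.950477 -0.034899
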