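#name Z1
#units principal property score (hydrophilicity)
#source Hellberg, Sjostrom, Skagerberg & Wold (1987) J Med Chem 30:1126-1135
A	0.07
R	2.88
N	3.22
D	3.64
C	0.71
Q	2.18
E	3.08
G	2.23
H	2.41
I	-4.44
L	-4.19
K	2.84
M	-2.49
F	-4.92
P	-1.22
S	1.96
T	0.92
W	-4.75
Y	-1.39
V	-2.69
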