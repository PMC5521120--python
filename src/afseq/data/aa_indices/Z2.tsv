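#name Z2
#units principal property score (steric bulk)
#source Hellberg, Sjostrom, Skagerberg & Wold (1987) J Med Chem 30:1126-1135
A	-1.73
R	2.52
N	1.45
D	1.13
C	-0.97
Q	0.53
E	0.39
G	-5.36
H	1.74
I	-1.68
L	-1.03
K	1.41
M	-0.27
F	1.30
P	0.88
S	-1.63
T	-2.09
W	3.65
Y	2.32
V	-2.53
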