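#name ECI
#units electronic charge index
#source Collantes & Dunn (1995) J Med Chem 38:2705-2713
A	0.05
R	1.69
N	1.31
D	1.25
C	0.15
Q	1.36
E	1.31
G	0.02
H	0.56
I	0.09
L	0.10
K	0.53
M	0.34
F	0.14
P	0.16
S	0.56
T	0.65
W	1.08
Y	0.72
V	0.07
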