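#name pa
#units normalized frequency (alpha helix)
#source Levitt (1978) Biochemistry 17:4277-4285; AAindex LEVM780101
A	1.29
R	0.96
N	0.90
D	1.04
C	1.11
Q	1.27
E	1.44
G	0.56
H	1.22
I	0.97
L	1.30
K	1.23
M	1.47
F	1.07
P	0.52
S	0.82
T	0.82
W	0.99
Y	0.72
V	0.91
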