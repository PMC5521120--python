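#name pt
#units normalized frequency (reverse turn)
#source Levitt (1978) Biochemistry 17:4277-4285; AAindex LEVM780103
A	0.77
R	0.88
N	1.28
D	1.41
C	0.81
Q	0.98
E	0.99
G	1.64
H	0.68
I	0.51
L	0.58
K	0.96
M	0.41
F	0.59
P	1.91
S	1.32
T	1.04
W	0.76
Y	1.05
V	0.47
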