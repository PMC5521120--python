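#name pb
#units normalized frequency (beta sheet)
#source Levitt (1978) Biochemistry 17:4277-4285; AAindex LEVM780102
A	0.90
R	0.99
N	0.76
D	0.72
C	0.74
Q	0.80
E	0.75
G	0.92
H	1.08
I	1.45
L	1.02
K	0.77
M	0.97
F	1.32
P	0.64
S	0.95
T	1.21
W	1.14
Y	1.25
V	1.49
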