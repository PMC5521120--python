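#name Xi
#units dimensionless (compatibility parameter; synthetic stand-in table)
#source synthetic: constructed stand-in for the Xi sequence-compatibility scale; not transcribed from a published scale
A	0.12
R	0.85
N	0.47
D	0.61
C	0.23
Q	0.43
E	0.58
G	0.33
H	0.66
I	-0.25
L	-0.21
K	0.72
M	-0.09
F	-0.31
P	0.39
S	0.29
T	0.18
W	-0.12
Y	0.04
V	-0.19
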