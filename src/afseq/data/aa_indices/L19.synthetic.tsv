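#name L19
#units dimensionless (compatibility parameter; synthetic stand-in table)
#source synthetic: constructed stand-in for the L1-9 sequence-compatibility scale, collapsed to one value per residue; not transcribed from a published scale
A	0.31
R	-0.42
N	-0.18
D	-0.27
C	0.52
Q	-0.11
E	-0.23
G	-0.05
H	0.14
I	0.78
L	0.69
K	-0.36
M	0.55
F	0.71
P	-0.48
S	-0.08
T	0.07
W	0.44
Y	0.28
V	0.74
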