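#name Mw
#units g/mol (free amino acid)
#source Standard free amino acid molecular masses; AAindex FASG760101
A	89.09
R	174.20
N	132.12
D	133.10
C	121.15
Q	146.15
E	147.13
G	75.07
H	155.16
I	131.17
L	131.17
K	146.19
M	149.21
F	165.19
P	115.13
S	105.09
T	119.12
W	204.23
Y	181.19
V	117.15
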