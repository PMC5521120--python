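#name Ap
#units A^2 (polar surface area; synthetic stand-in table)
#source synthetic: constructed stand-in approximating per-residue polar surface area; not transcribed from a published scale
A	41.4
R	119.9
N	96.9
D	104.8
C	47.6
Q	95.3
E	102.4
G	43.2
H	83.7
I	38.1
L	38.9
K	88.5
M	44.8
F	41.7
P	36.2
S	72.4
T	66.3
W	64.5
Y	78.2
V	39.6
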