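#name Z3
#units principal property score (electronic)
#source Hellberg, Sjostrom, Skagerberg & Wold (1987) J Med Chem 30:1126-1135
A	0.09
R	-3.44
N	0.84
D	2.36
C	4.13
Q	-1.14
E	-0.07
G	0.30
H	1.11
I	-1.03
L	-0.98
K	-3.14
M	-0.41
F	0.45
P	2.23
S	0.57
T	-1.40
W	0.85
Y	0.01
V	-1.29
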