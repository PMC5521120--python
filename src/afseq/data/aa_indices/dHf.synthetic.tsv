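#name dHf
#units kcal/mol (nonapeptide formation enthalpy; synthetic stand-in table)
#source synthetic: constructed stand-in for the Ala-flanked nonapeptide formation enthalpy scale; not transcribed from a published scale
A	-722.9
R	-641.3
N	-712.6
D	-718.4
C	-702.1
Q	-705.9
E	-711.2
G	-731.5
H	-668.7
I	-684.3
L	-686.1
K	-662.8
M	-679.5
F	-654.2
P	-697.4
S	-716.8
T	-709.3
W	-628.6
Y	-648.9
V	-691.7
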