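residue	volume_A3
A	67
C	86
D	91
E	109
F	135
G	48
H	118
I	124
K	135
L	124
M	124
N	96
P	90
Q	114
R	148
S	73
T	93
V	105
W	163
Y	141
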