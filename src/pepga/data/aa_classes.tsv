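residue	class
A	unpolar
V	unpolar
L	unpolar
I	unpolar
P	unpolar
F	unpolar
M	unpolar
W	unpolar
G	unpolar
S	polar
T	polar
C	polar
Y	polar
N	polar
Q	polar
K	basic
R	basic
H	basic
D	acidic
E	acidic
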