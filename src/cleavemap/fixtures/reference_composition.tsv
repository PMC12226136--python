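residue	percentage
A	7.01
R	5.64
N	3.59
D	4.74
C	2.30
Q	4.77
E	7.10
G	6.58
H	2.63
I	4.34
L	9.97
K	5.72
M	2.13
F	3.65
P	6.31
S	8.33
T	5.36
W	1.22
Y	2.66
V	5.96
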