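# Residue scales used by the amphiphilic pseudo-amino-acid composition:
# hydrophobicity (Tanford-style consensus scale) and hydrophilicity
# (Hopp-Woods). Both are standardized to zero mean / unit variance over
# the 20 residues before use.
residue	hydrophobicity	hydrophilicity
A	0.62	-0.5
C	0.29	-1.0
D	-0.90	3.0
E	-0.74	3.0
F	1.19	-2.5
G	0.48	0.0
H	-0.40	-0.5
I	1.38	-1.8
K	-1.50	3.0
L	1.06	-1.8
M	0.64	-1.3
N	-0.78	0.2
P	0.12	0.0
Q	-0.85	0.2
R	-2.53	3.0
S	-0.18	0.3
T	-0.05	-0.4
V	1.08	-1.5
W	0.81	-3.4
Y	0.26	-2.3
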