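# Per-residue covalent bond counts for the 20 free amino acids,
# derived from Kekule structures with explicit hydrogens
# (total bonds, bonds to hydrogen, single bonds, double bonds).
residue	total	hydrogen	single	double
A	12	7	11	1
C	13	7	12	1
D	15	7	13	2
E	18	9	16	2
F	23	11	19	4
G	9	5	8	1
H	20	9	17	3
I	21	13	20	1
K	23	14	22	1
L	21	13	20	1
M	19	11	18	1
N	16	8	14	2
P	17	9	16	1
Q	19	10	17	2
R	25	14	23	2
S	13	7	12	1
T	16	9	15	1
V	18	11	17	1
W	28	12	23	5
Y	24	11	20	4
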