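# Three-group physicochemical partitions of the 20 residues used by the
# composition/transition/distribution (CTD) descriptors. Standard partitions
# from the protein-fold descriptor literature (Dubchak-style attributes):
# HB hydrophobicity, VW normalized van der Waals volume, PO polarity,
# PZ polarizability, CH charge, SS secondary-structure propensity,
# SA solvent accessibility.
property	group1	group2	group3
HB	RKEDQN	GASTPHY	CLVIMFW
VW	GASTPDC	NVEQIL	MHKFRYW
PO	LIFWCMVY	PATGS	HQRKNED
PZ	GASDT	CPNVEQIL	KMHFRYW
CH	KR	ANCQGHILMFPSTWYV	DE
SS	EALMQKRH	VIYCWFT	GNPSD
SA	ALFCGIVW	RKQEND	MPSTHY
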