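# Toy Y-chromosome skeleton tree (minimal skeleton-tree content, reduced).
# Columns: node, parent, comma-separated defining SNP markers.
# European lineages fall on the F branch (P145/P160); E1b1a1 (P293) is the
# rare sub-Saharan outlier clade.
Y-ROOT
CT	Y-ROOT	M168
DE	CT	M145
E	DE	M96
E1b1a1	E	P293
CF	CT	P143
F	CF	M89,P145,P160
G	F	M201
HIJK	F	M578
H	HIJK	M69
IJK	HIJK	M523
I1	IJK	M253
K	IJK	M9
R1b	K	M343
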