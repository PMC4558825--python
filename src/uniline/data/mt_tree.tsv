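# Toy mtDNA haplogroup reference tree (Phylotree-style content, reduced).
# Columns: node, parent, comma-separated defining variant tokens.
# The haplogroup-B branch carries the Polynesian-motif 9-bp deletion
# (8281-8289d); clade labels follow the mtDNA haplogroup nomenclature.
ROOT
L3	ROOT	769,1018,10398,16223
M	L3	489,10400,14783
M28	M	1709,6620
Q	M	4117,16241
Q1	Q	8790
N	L3	8701,9540,10398!
R	N	12705,16223!
P	R	15607
P1	P	2746
R0	R	73
HV	R0	2706,7028
V	HV	4580,15904
H	HV	2581
H1	H	3010
H2	H	4769
H3	H	6776
B	R	8281-8289d,16189
B5	B	709,8584
B4	B	16217
B4a	B4	146,5465,6719
B4a1	B4a	14022
B4a1a	B4a1	80,10238
B4a1a1	B4a1a	12239
B4a1a1m	B4a1a1	151,1692,2416
B4a1a1a14	B4a1a1	151,1692,2416,6905
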