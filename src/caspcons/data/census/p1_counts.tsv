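# Published census of the P1 residue over all best-per-species vertebrate
# ortholog hits of human apoptotic caspase cleavage sites (328 species with
# well-represented proteomes). "Gap" = alignment gap at the P1 column,
# "Unknown" = ambiguity character, "D_or_N" = B ambiguity code.
category	count
D	562772
E	28423
N	5402
G	4771
A	1836
S	1772
Gap	1331
V	698
H	683
T	632
K	564
Q	535
Y	221
P	186
R	137
I	126
C	121
L	103
Unknown	45
F	33
M	33
D_or_N	2
W	1
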