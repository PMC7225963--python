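# Published census of the P1' residue (nascent N-terminus of the C-terminal
# cleavage fragment) in human cleavage sites and in their vertebrate ortholog
# hits, with the Arg/N-degron nature of each residue.
residue	nature	human_count	vertebrate_count
G	stabilizing	1080	171377
S	stabilizing	862	131638
A	stabilizing	505	80871
T	stabilizing	92	20011
L	destabilizing	91	18102
V	stabilizing	83	17729
F	destabilizing	80	13377
Y	destabilizing	74	14295
N	destabilizing	65	18225
D	destabilizing	53	11274
M	stabilizing	50	8552
E	destabilizing	46	9115
K	destabilizing	41	7301
I	destabilizing	40	7507
C	destabilizing	36	6986
H	destabilizing	31	6596
P	stabilizing	28	9298
Q	destabilizing	22	3929
R	destabilizing	22	6320
W	destabilizing	12	2754
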