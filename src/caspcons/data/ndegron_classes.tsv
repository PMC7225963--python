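# Arg/N-degron fate of a nascent N-terminal residue (the P1' residue of a
# caspase cleavage site becomes the N-terminus of the C-terminal fragment).
# mechanism: primary = bound directly by UBR-family N-recognins;
# secondary = destabilizing after Nt-arginylation by ATE1;
# tertiary = destabilizing after deamidation (N->D, Q->E) then arginylation;
# stabilizing = not recognized by the Arg/N-degron pathway (Nt-acetylation
# dependent fates are not modeled here).
residue	nature	mechanism
R	destabilizing	primary
K	destabilizing	primary
H	destabilizing	primary
L	destabilizing	primary
F	destabilizing	primary
Y	destabilizing	primary
W	destabilizing	primary
I	destabilizing	primary
D	destabilizing	secondary
E	destabilizing	secondary
C	destabilizing	secondary
N	destabilizing	tertiary
Q	destabilizing	tertiary
G	stabilizing	stabilizing
S	stabilizing	stabilizing
A	stabilizing	stabilizing
T	stabilizing	stabilizing
V	stabilizing	stabilizing
M	stabilizing	stabilizing
P	stabilizing	stabilizing
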