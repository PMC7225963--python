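# Published census of octamer Hamming distance (human cleavage site vs
# anchored ortholog octamer) cross-tabulated by whether the ortholog keeps
# aspartate at P1. D at P1 implies at least one matching position, so HD=8
# cannot occur in the aspartate stratum (and HD=0 not in the other).
p1_is_d	hd	count
True	0	346816
True	1	111584
True	2	57620
True	3	27071
True	4	12265
True	5	5380
True	6	1750
True	7	286
False	1	8894
False	2	11338
False	3	10704
False	4	7816
False	5	5074
False	6	2650
False	7	978
False	8	201
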