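#name: dna-tri-bend
#seqtype: DNA
#tuple: 3
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AAA -0.305
AAC -0.933
AAG -2.186
AAT -1.123
ACA -0.849
ACC -1.106
ACG 0.872
ACT -0.043
AGA 0.113
AGC -0.692
AGG 0.209
AGT -0.77
ATA 0.832
ATC 0.704
ATG -0.871
ATT -0.277
CAA -1.235
CAC -1.895
CAG -0.139
CAT 2.451
CCA -0.946
CCC -0.969
CCG 2.178
CCT -0.787
CGA 0.734
CGC -1.208
CGG -1.055
CGT 0.915
CTA 1.544
CTC 0.238
CTG 0.969
CTT 0.271
GAA 1.183
GAC 0.82
GAG 1.183
GAT 0.509
GCA 0.432
GCC 0.932
GCG -1.012
GCT 1.291
GGA 1.143
GGC -0.467
GGG 0.15
GGT 0.039
GTA -1.731
GTC -0.261
GTG -1.308
GTT 1.088
TAA 0.073
TAC -1.136
TAG -1.207
TAT -0.533
TCA 0.755
TCC -1.376
TCG 0.442
TCT -0.395
TGA 0.411
TGC 1.202
TGG -0.228
TGT 0.298
TTA -0.38
TTC -0.086
TTG 0.489
TTT 0.403
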