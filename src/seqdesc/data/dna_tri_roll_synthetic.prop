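#name: dna-tri-roll
#seqtype: DNA
#tuple: 3
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AAA -1.662
AAC 0.884
AAG -1.034
AAT 1.386
ACA 0.572
ACC 0.913
ACG -0.16
ACT 0.314
AGA 0.81
AGC -0.717
AGG 1.975
AGT 0.194
ATA -0.291
ATC -2.036
ATG 0.48
ATT 0.72
CAA 0.713
CAC -0.319
CAG 0.604
CAT 0.948
CCA -0.904
CCC 0.41
CCG -0.777
CCT -1.576
CGA -0.139
CGC 0.924
CGG -1.608
CGT 1.384
CTA -1.132
CTC -0.487
CTG -0.584
CTT 0.529
GAA 0.408
GAC -0.761
GAG 1.177
GAT 0.694
GCA -0.368
GCC 1.315
GCG -0.457
GCT -1.205
GGA 0.215
GGC 0.301
GGG 0.302
GGT 1.818
GTA 0.626
GTC 0.438
GTG -0.438
GTT -0.043
TAA -2.734
TAC 0.132
TAG 0.014
TAT -0.199
TCA 0.536
TCC -1.593
TCG -0.608
TCT 0.744
TGA 2.022
TGC -1.088
TGG -0.819
TGT 0.715
TTA 2.297
TTC -2.21
TTG 0.196
TTT -0.137
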