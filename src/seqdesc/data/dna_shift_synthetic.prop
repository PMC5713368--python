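#name: dna-shift
#seqtype: DNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -0.821
AC 1.983
AG -0.479
AT -0.511
CA -0.277
CC 0.782
CG -2.247
CT -1.174
GA -0.799
GC 2.622
GG 0.134
GT 0.904
TA -1.399
TC -0.498
TG 1.596
TT -0.363
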