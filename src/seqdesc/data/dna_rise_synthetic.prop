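#name: dna-rise
#seqtype: DNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -1.241
AC -1.076
AG -0.282
AT -1.044
CA -2.261
CC 0.717
CG 0.769
CT -0.192
GA 0.01
GC -0.038
GG 0.699
GT -0.803
TA -1.566
TC 0.196
TG 1.298
TT 0.773
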