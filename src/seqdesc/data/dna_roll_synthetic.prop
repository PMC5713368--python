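#name: dna-roll
#seqtype: DNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA 0.677
AC -0.83
AG 0.327
AT -2.372
CA 0.501
CC -0.124
CG -1.295
CT 0.173
GA 1.0
GC -0.563
GG -0.064
GT 0.383
TA 2.159
TC 0.804
TG -0.567
TT 0.472
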