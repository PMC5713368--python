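#name: dna-slide
#seqtype: DNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA 1.009
AC -0.301
AG 0.654
AT -0.813
CA 1.875
CC 1.546
CG 1.294
CT -0.042
GA 0.429
GC -0.304
GG 0.474
GT -0.82
TA 1.869
TC 0.08
TG 0.909
TT 0.825
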