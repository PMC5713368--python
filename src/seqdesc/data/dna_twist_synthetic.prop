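#name: dna-twist
#seqtype: DNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -0.202
AC 1.737
AG 1.413
AT 0.109
CA 0.181
CC 0.382
CG 0.505
CT 1.564
GA 1.31
GC 0.659
GG 1.172
GT -0.274
TA 0.044
TC 0.233
TG 0.131
TT -0.415
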