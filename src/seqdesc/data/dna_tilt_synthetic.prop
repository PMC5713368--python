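#name: dna-tilt
#seqtype: DNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -1.946
AC -0.399
AG -0.874
AT 0.952
CA -0.677
CC 1.303
CG 0.293
CT -0.05
GA 0.229
GC 1.554
GG 0.841
GT 1.407
TA -1.332
TC -1.858
TG -0.867
TT 1.166
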