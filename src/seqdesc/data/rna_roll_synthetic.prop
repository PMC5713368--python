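#name: rna-roll
#seqtype: RNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA 1.37
AC -0.571
AG 1.612
AU -0.872
CA 1.897
CC 0.147
CG 1.977
CU -0.19
GA 0.019
GC -1.213
GG 1.39
GU 2.83
UA -0.412
UC 1.047
UG 0.94
UU -0.7
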