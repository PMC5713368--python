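#name: rna-tilt
#seqtype: RNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -0.255
AC -0.169
AG -0.464
AU -0.424
CA 0.842
CC -0.022
CG -1.416
CU -0.431
GA 0.423
GC 0.771
GG -0.786
GU -0.432
UA 0.847
UC 0.399
UG 0.163
UU 0.118
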