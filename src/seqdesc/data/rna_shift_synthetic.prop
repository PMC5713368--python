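#name: rna-shift
#seqtype: RNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -1.339
AC 1.061
AG -1.279
AU -0.176
CA 0.628
CC 1.238
CG 1.076
CU -0.006
GA -1.023
GC 1.47
GG 1.153
GU -2.394
UA -0.494
UC -0.919
UG -0.923
UU 0.231
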