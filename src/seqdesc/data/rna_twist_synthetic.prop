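#name: rna-twist
#seqtype: RNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -0.611
AC -0.151
AG -0.068
AU -0.202
CA -2.529
CC 0.129
CG -0.591
CU -1.15
GA 0.597
GC 0.147
GG -0.148
GU 0.182
UA 0.148
UC 0.813
UG -1.765
UU -0.493
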