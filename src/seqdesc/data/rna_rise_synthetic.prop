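#name: rna-rise
#seqtype: RNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA 0.33
AC 0.686
AG -0.834
AU -0.1
CA 0.691
CC -1.271
CG 0.29
CU 0.221
GA -0.135
GC -1.217
GG -1.774
GU -1.21
UA -1.164
UC -0.424
UG -0.377
UU 0.045
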