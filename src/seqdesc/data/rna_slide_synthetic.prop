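#name: rna-slide
#seqtype: RNA
#tuple: 2
# SYNTHETIC stand-in values: representative of published helical-parameter compilations, not taken from any supplementary table. Suitable as defaults; replace with your own table for publication-grade work.
AA -1.631
AC 0.273
AG -0.316
AU 1.008
CA 0.846
CC -2.056
CG -1.529
CU 0.868
GA -0.288
GC 0.432
GG -0.975
GU 0.278
UA -1.091
UC 0.515
UG -0.493
UU 0.311
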