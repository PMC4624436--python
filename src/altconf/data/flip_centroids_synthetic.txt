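# Peptide flip cluster centroid geometries (synthetic
# reconstruction; canonical reference-peptide frame, angstroms).
cluster tweaked_down 180.0
CA1 0.3000 -0.9500 0.0000
C1 1.8250 -0.9539 -0.0000
O1 2.4582 -2.0095 0.0000
N2 2.3523 0.2139 -0.0000
CA2 3.8040 0.3500 0.0000
cluster simple_down 178.0
CA1 0.0000 -0.3000 0.0000
C1 1.4941 -0.6047 0.0186
O1 1.9062 -1.7639 0.0609
N2 2.3541 0.4531 -0.0132
CA2 3.8040 0.3000 0.0000
cluster left 122.0
CA1 0.0000 -0.2500 0.0000
C1 1.4542 -0.3257 0.4529
O1 1.7701 -0.9279 1.4791
N2 2.3815 0.2964 -0.3200
CA2 3.8040 0.3000 0.0000
cluster right -121.0
CA1 0.0000 -0.2500 0.0000
C1 1.4531 -0.3178 -0.4578
O1 1.7664 -0.9022 -1.4950
N2 2.3823 0.2908 0.3235
CA2 3.8040 0.3000 0.0000
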