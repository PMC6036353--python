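# Synthetic tissue-maximum-ratio fixture table for a 6 MV beam.
# Rows: depth (cm); columns: equivalent square field size (cm).
# Only the (10 cm, 10x10) entry enters the absolute-dose conversion.
depth\eq_square,4,6,10,15,20,30
1.5,1.000,1.000,1.000,1.000,1.000,1.000
5.0,0.920,0.925,0.930,0.935,0.940,0.945
10.0,0.715,0.726,0.739,0.760,0.770,0.785
15.0,0.560,0.580,0.600,0.620,0.635,0.655
20.0,0.440,0.460,0.480,0.500,0.520,0.545
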