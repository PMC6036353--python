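# Synthetic monitor-backscatter (Sb) lookup fixture, normalized so that
# Sb(10,10) = 1. Larger jaw openings expose less jaw area to the monitor
# chamber, so Sb decreases smoothly with field size. Rows: X field size (cm);
# columns: Y field size (cm).
x_size\y_size,2,4,6,10,15,20,30,40
2,1.00240,1.00210,1.00180,1.00120,1.00045,0.99970,0.99820,0.99670
4,1.00210,1.00180,1.00150,1.00090,1.00015,0.99940,0.99790,0.99640
6,1.00180,1.00150,1.00120,1.00060,0.99985,0.99910,0.99760,0.99610
10,1.00120,1.00090,1.00060,1.00000,0.99925,0.99850,0.99700,0.99550
15,1.00045,1.00015,0.99985,0.99925,0.99850,0.99775,0.99625,0.99475
20,0.99970,0.99940,0.99910,0.99850,0.99775,0.99700,0.99550,0.99400
30,0.99820,0.99790,0.99760,0.99700,0.99625,0.99550,0.99400,0.99250
40,0.99670,0.99640,0.99610,0.99550,0.99475,0.99400,0.99250,0.99100
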