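# Synthetic 10-bin approximation of a 6 MV bremsstrahlung spectrum.
# Fixture values for testing, not a beam-data claim.
# energy_MeV,probability
0.25,0.06
0.50,0.13
0.75,0.14
1.00,0.14
1.50,0.17
2.00,0.12
2.50,0.08
3.00,0.07
4.00,0.06
5.50,0.03
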