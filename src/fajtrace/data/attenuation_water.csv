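# Coarse water mass attenuation (mu/rho) and mass energy-absorption
# (mu_en/rho) coefficients, cm^2/g, for log-log interpolation.
# Fixture table at NIST-like values.
# energy_MeV,mu_over_rho,muen_over_rho
0.010,5.329,4.944
0.015,1.673,1.374
0.020,0.8096,0.5503
0.030,0.3756,0.1557
0.050,0.2269,0.04223
0.080,0.1837,0.02597
0.100,0.1707,0.02546
0.150,0.1505,0.02764
0.200,0.1370,0.02967
0.300,0.1186,0.03192
0.500,0.09687,0.03279
0.800,0.07865,0.03206
1.000,0.07072,0.03103
1.500,0.05754,0.02833
2.000,0.04942,0.02608
3.000,0.03969,0.02281
4.000,0.03403,0.02066
5.000,0.03031,0.01915
6.000,0.02770,0.01806
8.000,0.02429,0.01658
10.000,0.02219,0.01566
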