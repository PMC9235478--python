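# kappa calibration curve
# p=3
# n_sims=50000
# seed=1729
r	kappa
0.5	0.0
0.75	0.0
1.0	0.0
1.25	0.0
1.5	0.0
1.75	0.0
2.0	0.0
2.25	0.0
2.5	0.0
2.75	0.06744519028885154
3.0	0.2645040398334075
3.25	0.43578344515705547
3.5	0.5922774384351335
3.75	0.8028004697541322
4.0	0.9404780000216697
4.25	1.1018578889802375
4.5	1.2772825884434087
4.75	1.3975618009858974
5.0	1.4994773202586906
5.25	1.7022174100881278
5.5	1.823806392936098
5.75	1.997751124283119
6.0	2.1323112699111273
6.25	2.324163512450233
6.5	2.461640059470775
6.75	2.587682406101181
7.0	2.7158697045252986
7.25	2.8768684538123104
7.5	3.083294025139501
7.75	3.2457574472536366
8.0	3.419342980000777
8.25	3.5831478028417414
8.5	3.7174046079853933
8.75	3.951652254296196
9.0	4.182761133075654
9.25	4.301016681644902
9.5	4.6169688534570845
9.75	4.81367680269022
10.0	5.002452415791828
10.25	5.207951007644301
10.5	5.524168781210384
10.75	5.692064345309042
11.0	6.0651050932366966
11.25	6.1735584875770115
11.5	6.4969649325145005
11.75	6.761091249587286
12.0	7.011630910843777
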