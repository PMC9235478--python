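# kappa calibration curve
# p=6
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
2.75	0.0
3.0	0.0
3.25	0.0
3.5	0.0
3.75	0.0
4.0	0.027400850522641358
4.25	0.20741207443690093
4.5	0.3653892040877295
4.75	0.523847953104034
5.0	0.6636027241634268
5.25	0.809967696311187
5.5	0.9552484642966812
5.75	1.0608997166606404
6.0	1.189779542737964
6.25	1.3240050836258723
6.5	1.4322912835532222
6.75	1.557048247160378
7.0	1.6564726376908743
7.25	1.7938503154047518
7.5	1.887554002387938
7.75	2.022019456383142
8.0	2.1515645577119398
8.25	2.233102396979793
8.5	2.367380593612859
8.75	2.463218796041433
9.0	2.6357284360519833
9.25	2.7270701863490734
9.5	2.8988082360841063
9.75	2.991816967978381
10.0	3.1248199202344225
10.25	3.2385377732764646
10.5	3.3747809304321867
10.75	3.545155037552987
11.0	3.64977741553952
11.25	3.793757686346268
11.5	3.9362914969819203
11.75	4.068793887505985
12.0	4.2680361665405195
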