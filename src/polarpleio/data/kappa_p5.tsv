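# kappa calibration curve
# p=5
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
3.75	0.12242277782392967
4.0	0.2863586678194768
4.25	0.4397497239247403
4.5	0.5852524777690986
4.75	0.735319693493875
5.0	0.9241149125981021
5.25	1.0227741525787761
5.5	1.1924053677077389
5.75	1.3050404787009524
6.0	1.4126938695121023
6.25	1.5666857372466771
6.5	1.6841087079984773
6.75	1.801172938897623
7.0	1.9378069557213804
7.25	2.0550207707488695
7.5	2.1936557017346003
7.75	2.2953223487426917
8.0	2.4761816532216936
8.25	2.5736827873416486
8.5	2.701731899500749
8.75	2.7922747506894185
9.0	2.9571826873643015
9.25	3.116912600774897
9.5	3.2546691117188247
9.75	3.3878569208239298
10.0	3.4926385581920107
10.25	3.6959596021167758
10.5	3.8572394735393303
10.75	3.9995357229867707
11.0	4.129927974585181
11.25	4.274053677306746
11.5	4.522868475488189
11.75	4.5882217803079515
12.0	4.9012862699365725
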