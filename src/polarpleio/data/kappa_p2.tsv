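# kappa calibration curve
# p=2
# n_sims=50000
# seed=1729
r	kappa
0.5	0.0
0.75	0.0
1.0	0.013341800737518963
1.25	0.015356026807851397
1.5	0.027032735202321093
1.75	0.06185245348807928
2.0	0.17889728608217273
2.25	0.30463087290797963
2.5	0.4810956051004776
2.75	0.6453709534996691
3.0	0.8409908556433874
3.25	0.9811959564416646
3.5	1.1382514302456772
3.75	1.3383668716676704
4.0	1.4511699083776317
4.25	1.6405762610296177
4.5	1.7168119561414426
4.75	1.9757632032416252
5.0	2.0577289407025634
5.25	2.239128531962136
5.5	2.4269044769669756
5.75	2.6461699604955573
6.0	2.802931714260982
6.25	3.0071852176106613
6.5	3.190615708260277
6.75	3.398169273001718
7.0	3.562146612358991
7.25	3.686610042945783
7.5	4.041586290720433
7.75	4.164401079750907
8.0	4.48344633950197
8.25	4.6709070036616405
8.5	4.986888923905453
8.75	5.3399859804721705
9.0	5.577517806496779
9.25	5.577517806496779
9.5	5.959032892548857
9.75	6.451487444137767
10.0	6.975376301332442
10.25	6.975376301332442
10.5	7.24952631570052
10.75	7.779605241124229
11.0	8.107334542980382
11.25	8.291856344777273
11.5	8.741996080404672
11.75	9.13652646256015
12.0	9.320106226617884
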