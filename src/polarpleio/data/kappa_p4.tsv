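# kappa calibration curve
# p=4
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
3.25	0.020649475344207087
3.5	0.23161117815647048
3.75	0.4311032629432633
4.0	0.5837208004518194
4.25	0.7386756953580363
4.5	0.9031019775311712
4.75	1.0388994533871672
5.0	1.180299159451682
5.25	1.298364685649175
5.5	1.4677923975189806
5.75	1.562981787288282
6.0	1.722365446474592
6.25	1.8757123320361266
6.5	1.9737979581455443
6.75	2.105747022592983
7.0	2.260777676980827
7.25	2.4136527615349923
7.5	2.534592794558372
7.75	2.706728989888213
8.0	2.8566536368779114
8.25	2.96247549603463
8.5	3.091823979406429
8.75	3.3062243429321385
9.0	3.444935514973708
9.25	3.5432648627827863
9.5	3.7870432062673203
9.75	3.94832090654318
10.0	4.22389399963729
10.25	4.254144886388565
10.5	4.471506897552719
10.75	4.609380141605256
11.0	4.899393706540837
11.25	5.107939128614519
11.5	5.197842668621073
11.75	5.543435429803458
12.0	5.689820969963512
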