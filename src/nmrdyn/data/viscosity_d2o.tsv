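temperature_C	viscosity_mPa_s
5	1.9400
10	1.6490
15	1.4260
20	1.2467
25	1.0950
30	0.9694
35	0.8655
40	0.7770
45	0.7021
50	0.6380
55	0.5826
60	0.5347
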