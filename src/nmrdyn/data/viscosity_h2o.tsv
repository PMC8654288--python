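temperature_C	viscosity_mPa_s
5	1.5182
10	1.3059
15	1.1375
20	1.0016
25	0.8900
30	0.7972
35	0.7190
40	0.6527
45	0.5958
50	0.5465
55	0.5036
60	0.4660
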