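concentration_ug_ml,activity_percent,activity_sd
10,38.2,3.2
20,45.6,
40,72.8,
60,75.6,
100,88.9,2.9
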