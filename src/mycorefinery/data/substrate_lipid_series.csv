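substrate_conc,total_sugar,dry_weight,lipid_conc,lipid_content_printed,residual_sugar,consumed_sugar_printed,lipid_yield_printed
25,13.6 ± 1.0,5.4 ± 0.2,0.7 ± 0.1,13.7,6.3 ± 0.2,7.3 ± 0.3,29.6 ± 1.4
50,27.2 ± 0.8,9.2 ± 0.4,1.7 ± 0.4,18.8,9.5 ± 0.2,17.7 ± 1.4,34.6 ± 3.6
75,39.8 ± 2.1,11.5 ± 0.6,2.5 ± 0.7,21.4,14.9 ± 0.4,24.8 ± 2.3,32.8 ± 2.4
100,58.1 ± 1.8,14.1 ± 0.4,3.9 ± 0.3,27.6,29.0 ± 1.0,29.1 ± 0.7,38.9 ± 3.2
150,93.1 ± 3.2,12.0 ± 0.5,2.9 ± 0.4,24.2,47.1 ± 0.8,46.0 ± 4.2,19.4 ± 0.8
200,116.4 ± 2.0,8.5 ± 0.2,1.4 ± 0.2,15.9,78.3 ± 2.6,38.1 ± 2.3,6.8 ± 0.2
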