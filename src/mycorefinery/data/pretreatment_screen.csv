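treatment,chemical,chemical_conc,temperature_c,total_sugar,dry_weight,lipid_conc,lipid_content_printed,pigment_conc
Thermal,,,50,43.9 ± 1.2,11.5 ± 2.0,2.7 ± 0.1,23.7,4.6 ± 0.4
Thermal,,,121,56.6 ± 0.8,8 ± 2.3,3.9 ± 0.2,28.3,5.7 ± 0.2
Thermo-chemical,H2SO4,0.05,50,49.4 ± 1.1,15.5 ± 1.0,5.2 ± 0.3,33.3,7.1 ± 0.1
Thermo-chemical,H2SO4,0.05,121,63.1 ± 0.9,16.5 ± 0.4,5.4 ± 0.1,32.5,7.9 ± 0.1
Thermo-chemical,H2SO4,0.1,50,55.6 ± 0.3,12.1 ± 0.2,4.0 ± 0.3,32.8,6.4 ± 0.2
Thermo-chemical,H2SO4,0.1,121,71.9 ± 1.4,16.1 ± 0.0,5.4 ± 0.2,33.5,7.3 ± 0.2
Thermo-chemical,H2SO4,0.2,50,64.5 ± 2.1,16.0 ± 0.2,5.4 ± 0.1,34.0,6.9 ± 0.4
Thermo-chemical,H2SO4,0.2,121,82.4 ± 1.3,17.0 ± 0.2,6.5 ± 0.3,38.4,8.4 ± 0.1
Thermo-chemical,NaOH,0.5,50,61.1 ± 0.9,14.8 ± 0.4,3.6 ± 0.1,24.7,6.7 ± 0.1
Thermo-chemical,NaOH,0.5,121,65.0 ± 0.9,13.9 ± 0.5,3.8 ± 0.1,27.5,5.2 ± 0.4
Thermo-chemical,NaOH,1.0,50,60.9 ± 1.2,15.1 ± 0.3,4.2 ± 0.4,27.9,6.8 ± 0.1
Thermo-chemical,NaOH,1.0,121,70.4 ± 0.5,14.6 ± 0.4,4.7 ± 0.1,31.98,6.5 ± 0.2
Thermo-chemical,NaOH,1.5,50,63.0 ± 2.2,14.7 ± 0.2,4.5 ± 0.2,30.54,6.7 ± 0.1
Thermo-chemical,NaOH,1.5,121,74.8 ± 1.0,15.1 ± 0.5,5.0 ± 0.8,33.11,6.9 ± 0.1
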