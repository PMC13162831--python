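compound,percent_of_total,rt_min
"Propionic acid, 4-hydroxy-3-hexyl ester",7.926972909,12.353
2-Methylbutanoic anhydride,12.04358068,10.464
"3-Methyl-2-butenoic acid, 4-hexadecyl ester",14.71142521,11.557
"Butyric acid, 4-pentadecyl ester",4.776207303,16.644
1-Propoxypropan-2-yl 3-methylbutanoate,10.41224971,19.717
"2,5-Dimethyl-7,7-diphenyl-3-aza-4,6-dioxabicyclo[3.2.0]hept-2-ene",1.537102473,23.305
"8-Azabicyclo[3.2.1]octan-3-ol, 8-(2-hydroxy-2,2-diphenylethyl)-",48.61601885,26.772
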