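name,common_name,shorthand,percent,rt_min
"Dodecanoic acid, methyl ester",Methyl laurate,C12:0,8.497,22.17
Methyl tetradecanoate,Methyl myristate,C14:0,3.826,23.96
"Pentadecanoic acid, methyl ester",Methyl pentadecanoate,C15:0,1.841,24.96
"Hexadecanoic acid, methyl ester",Methyl palmitate,C16:0,20.156,26.24
"9-Hexadecenoic acid, methyl ester, (Z)-",Methyl palmitoleate (Z-9),C16:1,1.744,25.90
Methyl stearate,Methyl stearate,C18:0,8.289,29.42
"7-Octadecenoic acid, methyl ester",Methyl octadecenoate,C18:1,21.763,29.11
"9,12-Octadecadienoic acid, methyl ester",Methyl linoleate,C18:2,18.107,28.98
"Hexadecanoic acid, 15-methyl-, methyl ester",Branched heptadecanoate methyl ester (iso),br-C17:0,0.937,27.71
"Hexadecanoic acid, 2-hydroxy-, methyl ester",Hydroxypalmitate methyl ester,OH-C16:0,4.645,38.14
Methyl 18-methylnonadecanoate,Branched C20 methyl ester,br-C20:0,0.878,31.74
"2-Decenoic acid, methyl ester",Short-chain unsaturated methyl ester,C10:1,0.787,16.24
"7-Nonenoic acid, methyl ester",Short-chain unsaturated methyl ester,C9:1,6.337,20.77
"6-Heptenoic acid, methyl ester",Short-chain unsaturated methyl ester,C7:1,1.640,16.39
"Dodecanoic acid, 12-(4-methylphenylsulfonyloxy)-, methyl ester",Modified dodecanoate methyl ester,ts-C12:0,0.560,30.59
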