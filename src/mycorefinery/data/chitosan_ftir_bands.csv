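assignment,chitosan_cm1,composite_cm1
O-H and N-H stretching; H-bonding,3451.71,3412.67
Aliphatic C-H (-CH2/-CH3) stretch,,2931.60
CO2 (ambient),,2361.35
Amide I (C=O) with pi-pi/H-bond effects,1630.55,1627.43
CH2 bending (scissoring),,1415.41
CH3 bending/amide III contrib.,1383.77,1380.86
Amide III (C-N) + CH,1323.83,1326.41
C-O stretching (pyranose),,1281.01
C-N stretching/skeletal,,1261.01
C-O-C stretching (pyranose ring),1029.31,986.11
beta-1-4-glycosidic linkage vibration,,886.14
C-H out-of-plane; possible aromatic contribution,697.95,668.14
Low-freq skeletal/ring deformation,,589.25
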