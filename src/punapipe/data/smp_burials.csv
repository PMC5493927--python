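burial_id,bone_element,d18O_mw_vsmow,d13C_diet_vpdb,sex,age_min,age_max
1,parietal squama,-13.46,-22.35,ind,4,6
2,temporal petrous portion,-14.44,-23.95,m,30,40
3,left rib,-16.05,-20.08,f,18,20
4,left rib 1,-17.38,-21.24,ind,12,15
5,right rib,-16.93,-22.49,m,50,70
6,left meta-tarsal 5,-13.81,-21.74,f,35,45
7,left rib,-16.24,-21.14,f,18,20
8,right rib,-14.67,-20.69,f,30,40
9,right rib,-17.50,-21.28,m,20,30
10,thoracic vertebra neural arch,-15.10,-21.76,f,20,25
11,right rib,-15.69,-22.50,f,25,35
12,left rib,-12.92,-21.62,m,35,45
13,temporal petrous portion,-13.85,-23.73,ind,4,6
14,left femur,-14.72,-22.78,f,30,40
15,left proximal foot phalanx,-13.86,-23.47,f,35,45
16,left rib 3,-15.66,-22.50,m,35,45
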