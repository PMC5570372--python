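compound,level_nm,pe_pct,pe_sd,me_pct,me_sd,re_pct,re_sd
2H4-T0Ac,1.0,89,12,89,8,100,17
2H4-T1Ac,1.0,80,7,98,7,82,6
2H4-3-T1AM,1.0,76,6,90,7,85,7
"13C6-3,3'-T2",1.0,77,5,94,7,82,4
13C6-T3,1.0,80,6,93,3,85,7
13C6-rT3,1.0,66,7,88,6,75,6
13C6-T4,1.0,72,10,92,4,79,11
T0,1.0,72,3,87,2,82,3
3-T1,1.0,81,5,90,3,90,3
3'-T1,1.0,78,6,93,3,84,4
"3,5-T2",1.0,88,9,96,4,91,6
"3,3'-T2",1.0,79,4,93,3,85,2
"3',5'-T2",1.0,75,6,94,1,80,7
T3,1.0,74,2,91,2,81,4
rT3,1.0,70,5,89,4,79,5
T4,1.0,68,10,94,3,78,3
T0AM,1.0,84,8,97,2,87,8
3-T1AM,1.0,79,4,90,1,88,5
"3,5-T2AM",1.0,73,5,88,3,83,3
T3AM,1.0,69,1,82,11,84,9
rT3AM,1.0,64,4,81,10,80,10
T4AM,1.0,58,10,79,13,80,14
T0Ac,1.0,77,17,77,14,101,12
3-T1Ac,1.0,82,8,96,13,86,5
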