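compound,level_nm,pe_pct,pe_sd,me_pct,me_sd,re_pct,re_sd
2H4-3-T1AM,0.10,69,12,84,11,82,10
2H4-3-T1AM,12.5,69,10,82,9,81,13
2H4-3-T1AM,40.0,71,10,86,6,83,13
"13C6-3,3'-T2",0.10,73,8,87,8,85,8
"13C6-3,3'-T2",12.5,74,8,83,5,85,11
"13C6-3,3'-T2",40.0,75,9,87,6,86,11
13C6-T3,0.10,78,8,91,7,86,8
13C6-T3,12.5,80,8,88,5,89,11
13C6-T3,40.0,78,10,88,8,88,12
13C6-rT3,0.10,67,10,84,11,80,7
13C6-rT3,12.5,69,8,79,8,85,10
13C6-rT3,40.0,70,10,84,8,84,12
13C6-T4,0.10,67,13,84,13,80,10
13C6-T4,12.5,69,11,80,10,84,11
13C6-T4,40.0,68,10,81,10,85,12
T0,0.10,148,17,170,15,87,9
T0,12.5,71,8,91,7,76,12
T0,40.0,72,11,92,6,78,13
3-T1,0.10,78,10,85,8,91,8
3-T1,12.5,74,10,88,8,83,13
3-T1,40.0,75,10,90,7,84,11
3'-T1,0.10,74,9,84,12,88,10
3'-T1,12.5,70,9,84,7,81,10
3'-T1,40.0,73,10,87,7,84,13
"3,5-T2",12.5,81,10,96,8,83,12
"3,5-T2",40.0,80,11,94,6,86,10
"3,3'-T2",0.10,75,9,82,10,92,10
"3,3'-T2",12.5,73,9,87,6,84,10
"3,3'-T2",40.0,76,13,88,6,86,11
"3',5'-T2",0.10,70,13,80,13,88,11
"3',5'-T2",12.5,67,9,83,9,81,11
"3',5'-T2",40.0,71,10,86,7,82,11
T3,0.10,81,13,89,10,91,10
T3,12.5,72,11,87,8,81,12
T3,40.0,75,11,90,7,84,11
rT3,0.10,75,10,86,11,88,10
rT3,12.5,68,8,85,7,83,10
rT3,40.0,71,10,87,6,82,11
T4,0.10,72,20,83,18,86,12
T4,12.5,64,15,83,13,79,10
T4,40.0,68,15,86,9,79,12
T0AM,12.5,74,13,87,9,83,13
T0AM,40.0,77,13,90,7,84,12
3-T1AM,0.10,75,13,87,15,87,14
3-T1AM,12.5,69,11,87,8,78,13
3-T1AM,40.0,72,12,90,5,80,13
"3,5-T2AM",0.10,71,13,84,12,85,14
"3,5-T2AM",12.5,64,14,85,11,74,12
"3,5-T2AM",40.0,67,14,86,8,78,15
T3AM,0.10,64,26,77,33,85,19
T3AM,12.5,61,15,79,16,80,11
T3AM,40.0,66,13,84,9,78,16
rT3AM,0.10,63,14,80,14,79,19
rT3AM,12.5,59,15,79,11,79,11
rT3AM,40.0,62,16,81,8,76,18
T4AM,12.5,51,21,70,11,79,10
T4AM,40.0,60,21,74,15,73,24
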