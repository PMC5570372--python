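incubation_compound,incubated_pmol,time_min,compartment,compound,amount_pmol,detected
3-T1,775.9,5,cells,3-T1,32,1
3-T1,775.9,5,supernatant,3-T1,498,1
3-T1,775.9,5,cells,T0,1,1
3-T1,775.9,5,supernatant,T0,0.3,1
3-T1,775.9,10,cells,3-T1,34,1
3-T1,775.9,10,supernatant,3-T1,502,1
3-T1,775.9,10,cells,T0,1,1
3-T1,775.9,10,supernatant,T0,1,1
3-T1,775.9,30,cells,3-T1,39,1
3-T1,775.9,30,supernatant,3-T1,507,1
3-T1,775.9,30,cells,T0,2,1
3-T1,775.9,30,supernatant,T0,3,1
3-T1AM,812.7,5,cells,3-T1AM,238,1
3-T1AM,812.7,5,supernatant,3-T1AM,323,1
3-T1AM,812.7,5,cells,T0AM,1,1
3-T1AM,812.7,5,supernatant,T0AM,1,1
3-T1AM,812.7,5,cells,3-T1Ac,1,1
3-T1AM,812.7,5,supernatant,3-T1Ac,,0
3-T1AM,812.7,10,cells,3-T1AM,276,1
3-T1AM,812.7,10,supernatant,3-T1AM,333,1
3-T1AM,812.7,10,cells,T0AM,3,1
3-T1AM,812.7,10,supernatant,T0AM,2,1
3-T1AM,812.7,10,cells,3-T1Ac,1,1
3-T1AM,812.7,10,supernatant,3-T1Ac,,0
3-T1AM,812.7,30,cells,3-T1AM,334,1
3-T1AM,812.7,30,supernatant,3-T1AM,329,1
3-T1AM,812.7,30,cells,T0AM,3,1
3-T1AM,812.7,30,supernatant,T0AM,6,1
3-T1AM,812.7,30,cells,3-T1Ac,1,1
3-T1AM,812.7,30,supernatant,3-T1Ac,9,1
3-T1Ac,777.6,5,cells,3-T1Ac,4,1
3-T1Ac,777.6,5,supernatant,3-T1Ac,596,1
3-T1Ac,777.6,5,cells,T0Ac,1,1
3-T1Ac,777.6,5,supernatant,T0Ac,,0
3-T1Ac,777.6,10,cells,3-T1Ac,4,1
3-T1Ac,777.6,10,supernatant,3-T1Ac,599,1
3-T1Ac,777.6,10,cells,T0Ac,1,1
3-T1Ac,777.6,10,supernatant,T0Ac,8,1
3-T1Ac,777.6,30,cells,3-T1Ac,3,1
3-T1Ac,777.6,30,supernatant,3-T1Ac,632,1
3-T1Ac,777.6,30,cells,T0Ac,1,1
3-T1Ac,777.6,30,supernatant,T0Ac,14,1
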