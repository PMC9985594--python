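priority,therapy_class,dose_band,requires_class,step
10,biologic,any,,5
20,ICS_LABA,high,,5
30,ICS_LABA,medium,,4
40,ICS,high,,4
50,ICS_LABA,low,,3
60,ICS,medium,,3
70,ICS,low,LTRA,3
80,ICS,low,,2
90,ICS,any,,2
100,LTRA,any,,2
110,SABA,any,,1
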