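patient_id,phase,tre_manual,tre_semiauto
LR01,1,15.4,NA
LR02,1,22.7,NA
LS03,1,24.6,NA
LS04,1,5.9,NA
LS06,1,16.1,NA
LS07,1,10.0,NA
LR04,2,9.2,10.4
LS05,2,10.6,8.7
LS08,2,17.5,16.8
LR06,2,9.8,9.8
LR07,2,12.5,20.8
LS09,2,16.1,11.6
LS10,2,9.6,11.1
LS11,2,12.9,16.8
LS15,2,2.8,13.0
LR08,2,8.0,19.9
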