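diet,genotype,sex,count
CTRL,APOE2,Male,6
HFD,APOE2,Female,4
HFD,APOE2,Male,5
CTRL,APOE2HN,Female,3
CTRL,APOE2HN,Male,3
HFD,APOE2HN,Female,3
HFD,APOE2HN,Male,3
CTRL,APOE3,Female,5
CTRL,APOE3,Male,3
HFD,APOE3,Female,4
HFD,APOE3,Male,10
CTRL,APOE3HN,Female,3
CTRL,APOE3HN,Male,3
HFD,APOE3HN,Female,7
HFD,APOE3HN,Male,7
CTRL,APOE4,Female,3
CTRL,APOE4,Male,3
HFD,APOE4,Female,2
HFD,APOE4,Male,7
CTRL,APOE4HN,Female,4
CTRL,APOE4HN,Male,7
HFD,APOE4HN,Female,5
HFD,APOE4HN,Male,4
CTRL,APOE KO,Female,4
CTRL,APOE KO,Male,5
HFD,APOE KO,Female,6
HFD,APOE KO,Male,4
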