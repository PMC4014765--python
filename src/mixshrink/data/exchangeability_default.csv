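chemical,intercept,DBP_metabolites,DEHP_metabolites,BFR,PFAS,PCB,OC_pesticide,persistent
MBP,1,1,0,0,0,0,0,0
MiBP,1,1,0,0,0,0,0,0
MEP,1,0,0,0,0,0,0,0
MBzP,1,0,0,0,0,0,0,0
MCPP,1,0,0,0,0,0,0,0
MEHP,1,0,1,0,0,0,0,0
MEHHP,1,0,1,0,0,0,0,0
MECPP,1,0,1,0,0,0,0,0
BPA,1,0,0,0,0,0,0,0
PCB-28,1,0,0,0,0,1,0,1
PCB-66,1,0,0,0,0,1,0,1
PCB-74,1,0,0,0,0,1,0,1
PCB-99,1,0,0,0,0,1,0,1
PCB-101,1,0,0,0,0,1,0,1
PCB-105,1,0,0,0,0,1,0,1
PCB-118,1,0,0,0,0,1,0,1
PCB-138/158,1,0,0,0,0,1,0,1
PCB-146,1,0,0,0,0,1,0,1
PCB-153,1,0,0,0,0,1,0,1
PCB-156,1,0,0,0,0,1,0,1
PCB-157,1,0,0,0,0,1,0,1
PCB-167,1,0,0,0,0,1,0,1
PCB-170,1,0,0,0,0,1,0,1
PCB-172,1,0,0,0,0,1,0,1
PCB-177,1,0,0,0,0,1,0,1
PCB-178,1,0,0,0,0,1,0,1
PCB-183,1,0,0,0,0,1,0,1
PCB-187,1,0,0,0,0,1,0,1
PCB-194,1,0,0,0,0,1,0,1
PCB-195,1,0,0,0,0,1,0,1
PCB-196/203,1,0,0,0,0,1,0,1
PCB-199,1,0,0,0,0,1,0,1
PCB-206,1,0,0,0,0,1,0,1
PCB-209,1,0,0,0,0,1,0,1
beta-HCH,1,0,0,0,0,0,1,1
HCB,1,0,0,0,0,0,1,1
pp-DDT,1,0,0,0,0,0,1,1
pp-DDE,1,0,0,0,0,0,1,1
oxychlordane,1,0,0,0,0,0,1,1
trans-nonachlor,1,0,0,0,0,0,1,1
BB-153,1,0,0,1,0,0,0,1
PBDE-28,1,0,0,1,0,0,0,1
PBDE-47,1,0,0,1,0,0,0,1
PBDE-85,1,0,0,1,0,0,0,1
PBDE-99,1,0,0,1,0,0,0,1
PBDE-100,1,0,0,1,0,0,0,1
PBDE-153,1,0,0,1,0,0,0,1
PBDE-154,1,0,0,1,0,0,0,1
PFOA,1,0,0,0,1,0,0,1
PFOS,1,0,0,0,1,0,0,1
PFNA,1,0,0,0,1,0,0,1
PFHxS,1,0,0,0,1,0,0,1
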