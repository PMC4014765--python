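name,chem_class,matrix,metabolite_group,pct_above_lod,gm,gsd,p5,p25,p50,p75,p95,nhanes_median
MBP,phthalate,urine,DBP,100,26.0,1.9,9.5,18,26,37,75,24
MiBP,phthalate,urine,DBP,99,5.1,2.1,1.5,3.0,5.6,8.6,17,4.0
MEP,phthalate,urine,,100,143.3,2.9,25,70,133,286,1010,120
MBzP,phthalate,urine,,98,10.3,2.4,3.2,5.8,11,17,48,10
MCPP,phthalate,urine,,99,2.4,1.8,1.1,1.6,2.3,3.4,5.9,2.9
MEHP,phthalate,urine,DEHP,89,5.2,2.7,,2.9,4.4,7.5,41,2.2
MEHHP,phthalate,urine,DEHP,100,41.0,2.4,7.7,15,22,49,152,19
MECPP,phthalate,urine,DEHP,100,27.6,2.5,13,21,35,70,191,31
BPA,phenol,urine,,96,2.1,1.9,0.8,1.4,2.0,3.1,6.6,2.7
PCB-28,PCB,serum,,82,0.8,2.9,,0.7,1.0,1.6,3.3,5.0
PCB-66,PCB,serum,,75,5.6,2.7,,,0.6,1.0,2.2,1.4
PCB-74,PCB,serum,,99,2.8,1.8,1.2,2.0,2.6,3.9,7.0,5.4
PCB-99,PCB,serum,,99,2.8,1.8,1.2,1.9,2.8,3.9,7.1,3.9
PCB-101,PCB,serum,,32,2.1,2.9,,,,0.5,1.5,1.6
PCB-105,PCB,serum,,93,1.1,2.5,,0.8,1.1,1.7,3.4,1.2
PCB-118,PCB,serum,,99,4.9,2.0,2.1,3.2,4.8,7.1,14,5.0
PCB-138/158,PCB,serum,,99,7.8,2.0,3.0,5.3,7.7,11,25,16
PCB-146,PCB,serum,,93,1.0,2.6,,0.8,1.1,1.7,4.1,2.3
PCB-153,PCB,serum,,100,11.1,1.9,4.3,7.6,11,15,35,22
PCB-156,PCB,serum,,96,1.6,2.4,0.5,1.0,1.6,2.5,6.1,3.4
PCB-157,PCB,serum,,51,3.3,3.2,,,0.4,0.7,1.6,0.9
PCB-167,PCB,serum,,59,3.9,3.1,,,0.5,0.7,1.8,0.9
PCB-170,PCB,serum,,100,2.8,2.2,0.9,1.8,2.8,4.2,9.4,6.3
PCB-172,PCB,serum,,34,2.2,3.0,,,,0.5,1.2,0.9
PCB-177,PCB,serum,,61,4.0,3.1,,,0.5,0.7,2.1,1.3
PCB-178,PCB,serum,,52,3.3,3.2,,,0.4,0.7,1.8,1.2
PCB-183,PCB,serum,,87,0.8,3.0,,0.6,1.0,1.4,2.8,1.7
PCB-187,PCB,serum,,98,2.1,2.3,0.7,1.5,2.1,3.3,7.1,4.6
PCB-194,PCB,serum,,92,1.2,2.8,,0.9,1.4,2.2,4.5,4.0
PCB-195,PCB,serum,,39,2.4,3.1,,,,0.6,1.1,0.6
PCB-196/203,PCB,serum,,96,1.6,2.3,0.5,1.1,1.6,2.5,4.8,3.3
PCB-199,PCB,serum,,93,1.2,2.8,,0.9,1.3,2.2,4.4,3.7
PCB-206,PCB,serum,,81,0.6,3.2,,0.6,0.8,1.2,2.4,2.3
PCB-209,PCB,serum,,35,2.2,3.0,,,,0.5,1.0,1.2
beta-HCH,OC_pesticide,serum,,27,1.9,2.8,,,,1.9,4.4,
HCB,OC_pesticide,serum,,94,6.5,1.9,,5.5,7.0,9.0,13.8,16
pp-DDT,OC_pesticide,serum,,52,3.3,3.2,,,1.9,3.2,6.2,
pp-DDE,OC_pesticide,serum,,100,71.6,1.8,31,51,67,93,182,206
oxychlordane,OC_pesticide,serum,,90,4.4,2.5,,3.5,5.1,7.2,13,11
trans-nonachlor,OC_pesticide,serum,,97,7.5,2.1,2.3,5.1,7.4,12,25,15
BB-153,BFR,serum,,85,0.9,3.7,,0.6,1.1,1.9,4.5,2.0
PBDE-28,BFR,serum,,81,0.8,4.0,,0.5,1.1,1.8,4.2,1.0
PBDE-47,BFR,serum,,100,20.1,2.7,4.9,9.7,19,35,103,19
PBDE-85,BFR,serum,,49,3.1,3.2,,,,1.0,3.5,
PBDE-99,BFR,serum,,100,4.7,2.9,1.0,2.2,4.4,8.0,33,
PBDE-100,BFR,serum,,99,3.8,3.0,0.9,2.0,3.4,7.9,25,3.2
PBDE-153,BFR,serum,,99,5.1,3.1,1.3,2.4,4.2,9.0,54,4.0
PBDE-154,BFR,serum,,42,2.6,3.1,,,,0.9,2.8,0.8
PFOA,PFAS,serum,,100,5.6,1.7,2.5,3.8,5.5,7.6,13,3.6
PFOS,PFAS,serum,,100,13.1,1.6,5.7,9.3,13,18,27,18
PFNA,PFAS,serum,,100,0.9,1.5,0.5,0.7,0.9,1.2,1.9,0.9
PFHxS,PFAS,serum,,100,1.5,2.0,0.5,0.9,1.6,2.4,5.0,1.6
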