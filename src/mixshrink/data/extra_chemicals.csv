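name,chem_class,matrix,metabolite_group,pct_above_lod,gm,gsd,correlated_with,corr
PCB-180,PCB,serum,,99,2.0,2.2,PCB-170,0.97
MEOHP,phthalate,urine,DEHP,100,15.0,2.4,MEHHP,0.97
PCB-44,PCB,serum,,8,0.2,2.5,,
PCB-49,PCB,serum,,6,0.2,2.5,,
PCB-52,PCB,serum,,12,0.3,2.6,,
PCB-87,PCB,serum,,5,0.2,2.4,,
PCB-110,PCB,serum,,10,0.2,2.6,,
PCB-128,PCB,serum,,7,0.2,2.5,,
PCB-149,PCB,serum,,9,0.2,2.6,,
PCB-151,PCB,serum,,11,0.2,2.5,,
dieldrin,OC_pesticide,serum,,14,1.2,2.2,,
mirex,OC_pesticide,serum,,10,0.8,2.7,,
heptachlor-epoxide,OC_pesticide,serum,,12,1.0,2.3,,
PBDE-17,BFR,serum,,8,0.3,3.0,,
PBDE-66,BFR,serum,,11,0.3,3.1,,
PBDE-183,BFR,serum,,13,0.4,3.2,,
PFDeA,PFAS,serum,,9,0.2,1.9,,
PFDoA,PFAS,serum,,6,0.1,2.0,,
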