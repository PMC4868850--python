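symbol,direction
Anp32b,up
C4a,up
Chi3l1,up
Clu,up
Daam2,up
Enah,up
Fgfr1,up
Gfap,up
Hipk2,up
Maob,up
Map4,up
Map7,up
Mid1ip1,up
Moxd1,up
Mxi1,up
Plekhb1,up
Ptk2b,up
Rassf2,up
Ssfa2,up
Sun2,up
Zcchc24,up
Adamts8,down
Agfg1,down
Cacna1g,down
Cask,down
Cdh11,down
Cdh8,down
Cdk5,down
Crh,down
Crhr1,down
Cx3cl1,down
Cyp26b1,down
Dcaf7,down
Dnajb5,down
Dusp14,down
Edn3,down
Egr4,down
Eif4g1,down
Fam131a,down
Fam49a,down
Gabra4,down
Gng4,down
Grm2,down
Hmgcs1,down
Htr2a,down
Kcnf1,down
Kcnh1,down
Lancl2,down
Large,down
Lppr4,down
Mapk4,down
Mmd,down
Neto2,down
Rprm,down
Sel1l3,down
Slc8a2,down
Sst,down
Sstr1,down
St8sia3,down
Trib2,down
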