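Bcl6b
Bcor
Cebpb
Cebpd
Dnajb5
Fos
Fosb
Jun
Mxd3
Meis1
Nab2
Smarcal1
Tsc22d3
Ccdc101
Cry2
Csrnp1
Dlx1
Egr1
Egr2
Egr3
Egr4
Fosl2
Hes3
Hmox1
Ing3
Eomes
Kdm6b
Jmjd6
Junb
Mnt
Mef2b
Npas1
Npas4
Nfkbia
Nr4a1
Nr4a2
Pax1
Per1
Rxra
Srf
Sim2
Timeless
Tle3
Trib1
Mafk
Mycn
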