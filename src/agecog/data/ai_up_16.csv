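symbol,ai_vs_au_fold,age_fold
Arc,1.89,-1.19
Bhlhe40,1.22,-1.08
Btg2,1.49,-1.28
Dusp1,1.45,-1.27
Egr1,1.57,-1.31
Egr2,2.79,-1.37
Egr4,1.53,-1.41
Hspa1a,2.12,-1.26
Hspa1b,1.84,-1.46
Ier5,1.29,-1.17
Junb,1.50,-1.36
Klf10,1.36,-1.29
Nr4a1,1.60,-1.23
Nr4a3,1.39,-1.20
Ptgs2,1.36,-1.12
Sik1,1.76,-1.12
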