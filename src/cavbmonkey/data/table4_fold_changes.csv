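category,gene,probe,fold_change
Ion channels,SCN5A,1,0.85
Ion channels,KCNQ1,1,0.95
Ion channels,SCN7A,1,1.21
Ion channels,KCNJ2,1,2.00
Ion channels,SCN1B,1,1.17
Ion channels,KCNE1,1,1.05
Ion channels,SCN2B,1,1.39
Ion channels,KCNMB4,1,2.04
Ion channels,KCNJ5,1,0.60
Ion channels,CACNA1D,1,3.39
Ion channels,KCNJ8,1,0.59
Ion channels,CACNA1C,1,0.99
Ion channels,KCNH2,1,0.88
Ion channels,CACNB1,1,1.85
"Pumps, exchanger, connexins",ATP2A2,1,0.91
"Pumps, exchanger, connexins",GJA1,1,1.10
"Pumps, exchanger, connexins",RYR2,1,1.14
"Pumps, exchanger, connexins",GJC1,1,0.83
"Pumps, exchanger, connexins",SLC8A1,1,0.73
"Pumps, exchanger, connexins",GJA5,1,1.51
Ca2+-handling proteins,CAMK1D,1,2.06
Ca2+-handling proteins,PLN,1,1.14
Ca2+-handling proteins,CAMK2A,1,0.67
Ca2+-handling proteins,CALM3,1,0.77
Ca2+-handling proteins,CAMK2B,1,1.27
Ca2+-handling proteins,CASQ2,1,1.70
Ca2+-handling proteins,CAMK2D,1,1.05
Receptors,ADRB2,1,1.68
Receptors,ADRB1,1,0.65
Fibrosis,SERPINE2,1,2.67
Fibrosis,FN1,1,2.52
Fibrosis,SERPINE2,2,2.14
Fibrosis,THBS1,1,3.46
Fibrosis,SERPINE2,3,2.25
Cardiac hypertrophy,TNFSF12/TWEAK,1,2.44
Cardiac hypertrophy,TNFRSF12A,1,3.20
"Fibrosis, hypertrophy, apoptosis",ANKRD1,1,3.11
IFN-stimulated cytokine,IFI27,1,0.47
IFN-stimulated cytokine,IFIT2,1,0.47
Others,TMEM14C,1,0.39
Others,RPL35A,1,2.70
Others,TPT1/TPCT1,1,0.67
Others,SDF2,1,0.60
Others,LPL,1,0.57
Others,USP14,1,1.74
Others,DEFB1/RHBD-1,1,0.65
Others,USP14,2,1.73
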