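compound_no,drug,target,rv2d,rv3d,z2d,z3d
1,DMSO,Vehicle control,100.00,100.00,2.41,-0.13
2,AEE788 (NVP-AEE788),EGFR,2.43,100.89,-0.82,-0.09
3,Afatinib (BIBW2992),EGFR,1.15,102.56,-0.87,-0.02
4,BMS-599626 (AC480),EGFR,43.20,127.70,0.53,1.06
5,Erlotinib HCl,"EGFR, HER2",45.53,117.10,0.60,0.61
6,"Dacomitinib (PF299804,PF-00299804)",EGFR,4.09,109.62,-0.77,0.29
7,Gefitinib (Iressa),EGFR,9.50,83.83,-0.59,-0.82
8,Lapatinib,HER1/EGFR,0.26,53.94,-0.90,-2.11
9,Neratinib (HKI-272),EGFR,24.35,131.12,-0.10,1.21
10,CI-1033 (Canertinib),"EGFR, HER2",29.54,113.00,0.07,0.43
11,CO-1686,"EGFR, HER2",1.12,111.65,-0.87,0.37
12,BKM120 (NVP-BKM120),mTOR,4.31,119.83,-0.76,0.73
13,BYL719,AKT1/2/3,6.16,71.72,-0.70,-1.35
14,XL147,PI3K/mTOR,8.89,41.65,-0.61,-2.64
15,Everolimus (RAD001),PI3K,48.00,62.52,0.69,-1.74
16,AZD2014,PI3K,14.85,124.21,-0.41,0.91
17,PF-05212384 (PKI-587),mTOR,12.73,109.42,-0.48,0.28
18,XL765 (SAR245409),PI3K/mTOR,14.84,106.63,-0.41,0.16
19,BEZ235,PI3K,30.38,75.99,0.10,-1.16
20,AZD5363,PI3K/mTOR,5.66,96.35,-0.72,-0.29
21,ABT-199 (GDC-0199),Bcl-2,4.16,106.37,-0.77,0.15
22,ABT-888 (Veliparib),PARP,94.62,101.98,2.23,-0.04
23,AUY922 (NVP-AUY922),HSP (e.g. HSP90),11.90,117.39,-0.51,0.62
24,Axitinib,"VEGFR1/2/3, PDGFRβ and c-Kit",62.44,93.55,1.16,-0.41
25,AZD4547,FGFR1/2/3,6.04,68.38,-0.70,-1.49
26,AZD6244 (Selumetinib),MEK1,13.94,98.79,-0.44,-0.18
27,LGK-974,PORCN,45.28,65.18,0.60,-1.63
28,BGJ398 (NVP-BGJ398),FGFR1/2/3,40.05,108.39,0.42,0.23
29,Bortezomib (Velcade),Proteasome,0.78,99.46,-0.88,-0.15
30,Cediranib (AZD2171),"VEGFR, FIT",41.62,93.29,0.47,-0.42
31,Crizotinib (PF-02341066),"Met, ALK",0.21,83.71,-0.90,-0.83
32,Dasatinib (BMS-354825),Bcr-Abl,0.29,97.98,-0.89,-0.22
33,Dovitinib (TKI-258),"Flt3, c-Kit, FGFR1/3, VEGFR1/2/3, PDGFRα/β",2.32,109.48,-0.83,0.28
34,Imatinib (Gleevec),"v-Abl,/2/bl, c-Kit and PDGFR",17.25,101.08,-0.33,-0.08
35,INCB28060,Met,99.82,105.92,2.40,0.13
36,LY2835219,CDK4/6,0.00,104.67,-0.90,0.07
37,DMSO,Vehicle control,90.87,110.86,2.11,0.34
38,Cabozantinib (XL184),"VEGFR2, c-Met, Ret, Kit, Flt-1/3/4, Tie2, AXL",33.54,117.28,0.21,0.62
39,Foretinib (XL880),"HGFR, VEGFR, mostly for Met and KDR",0.19,67.17,-0.90,-1.54
40,Ibrutinib,"Btk, modestly potent to Bmx, CSK, FGR, BRK, HCK, less potent to EGFR, Yes, ErbB2, JAK3",1.35,118.02,-0.86,0.65
41,vemurafenib,B-RafV600E,20.06,125.60,-0.24,0.97
42,trametinib,MEK1/2,21.47,102.57,-0.19,-0.02
43,"LDE225 (NVP-LDE225, Erismodegib)",Smoothened,56.25,89.87,0.96,-0.56
44,LDK378,ALK,0.00,58.08,-0.90,-1.93
45,LEE011,CDK4/6,51.67,122.27,0.81,0.83
46,Nilotinib (AMN-107),Bcr-Abl,56.07,118.79,0.95,0.68
47,Olaparib (AZD2281),PARP1/2,37.94,115.78,0.35,0.55
48,Panobinostat (LBH589),HDAC,3.88,98.51,-0.78,-0.19
49,Pazopanib HCl,"VEGFR1/2/3, PDGFR. FGFR, c-Kit",15.29,82.24,-0.40,-0.89
50,PD 0332991 (Palbociclib HCl),CDK4/6,2.50,103.25,-0.82,0.01
51,PF-04449913,HSP90,79.62,120.25,1.73,0.74
52,Sotrastaurin (AEB071),PKC,9.61,127.05,-0.59,1.04
53,Sunitinib Malate (Sutent),VEGFR2 and PDGFRβ,0.44,145.45,-0.89,1.83
54,Tandutinib (MLN518),"FLT3, PDGFR, FGFR, c-Kit",4.88,124.95,-0.74,0.95
55,Tivozanib (AV-951),"VEGFR, c-Kit, PDGFR",3.45,126.12,-0.79,1.00
56,Vismodegib (GDC-0449),Hedgehog/smoothend,84.88,135.80,1.91,1.41
57,PHA-665752,c-Met inhibitor,0.70,152.10,-0.88,2.12
58,Dabrafenib,BRAFV600,7.44,104.66,-0.66,0.07
59,Regorafenib,"VEGFR1/2/3, PDGFR, Kit, RET and Raf-1",0.33,24.48,-0.89,-3.38
60,Bosutinib,dual Src/Abl,1.52,120.82,-0.85,0.77
61,Carfilzomib,Proteasome,5.90,100.08,-0.71,-0.12
62,Ruxolitinib,JAK1/2,20.07,92.76,-0.24,-0.44
63,Vandetanib,VEGFR2,53.28,121.35,0.86,0.79
64,TMZ,alkylating agent,79.39,122.68,1.73,0.85
65,Amorolfine,"morpholine antifungal drug, fungal enzymes D14 reductase and D7-D8 isomerase",102.84,116.49,2.50,0.58
66,Mevastatin,HMG-CoA reductase inhibitor,88.37,98.91,2.02,-0.17
67,Amiodarone,antiarrhythmic medication. β- and γ-secretase,48.89,99.38,0.72,-0.15
68,Fluvastatin Na,Anticholesterol agent. HMG-CoA inhibitor,64.15,98.83,1.22,-0.18
69,Mycophenolic acid,inosine-5'-monophosphate dehydrogenase inhibitor,24.47,132.11,-0.09,1.25
70,Raloxifene HCl,estrogen receptor inhibitor,21.44,128.87,-0.19,1.12
71,Astemizole,histamine receptor ligand,24.43,99.87,-0.09,-0.13
72,Fenretinide,retinoic acid receptor ligand,0.14,75.31,-0.90,-1.19
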