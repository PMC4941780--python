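taxon,specimen_label,source_ref,group,life_stage,wing_length_m,span_m,mass_method,mass_label,mass_kg,area_m2,loading_N_m2,feathers_estimated,paravian
Anchiornis huxleyi,BMNHC PH828,Li et al. 2010,nonavian,juvenile,0.16,0.33,femur_CF,CF,0.09,0.01,70,False,True
Anchiornis huxleyi,LPM B00169,Sullivan et al. 2014,nonavian,adult,0.24,0.5,femur_CF,CF,0.38,0.03,146,False,True
Archaeopteryx lithographica,11th,Foth et al. 2014,avialan,adult,0.31,0.65,humerus_Liu,Liu,0.24,0.06,38,False,True
Archaeopteryx lithographica,11th,Foth et al. 2014,avialan,adult,0.31,0.65,humerus_Fe,Fe,0.36,0.06,57,False,True
Archaeopteryx lithographica,Berlin,Mayr et al. 2007,avialan,adult,0.29,0.61,humerus_Liu,Liu,0.23,0.06,38,False,True
Archaeopteryx lithographica,Berlin,Mayr et al. 2007,avialan,adult,0.29,0.61,humerus_Fe,Fe,0.32,0.06,55,False,True
Archaeopteryx lithographica,London,Elzanowski 2002,avialan,adult,0.33,0.69,humerus_Liu,Liu,0.31,0.07,45,False,True
Archaeopteryx lithographica,London,Elzanowski 2002,avialan,adult,0.33,0.69,humerus_Fe,Fe,0.48,0.07,70,False,True
Archaeopteryx lithographica,Munich,Mayr et al. 2007 and Wellnhofer 1993,avialan,adult,0.26,0.55,humerus_Liu,Liu,0.18,0.05,38,False,True
Archaeopteryx lithographica,Munich,Mayr et al. 2007 and Wellnhofer 1993,avialan,adult,0.26,0.55,humerus_Fe,Fe,0.25,0.05,53,False,True
Archaeopteryx lithographica,Thermopolis,Mayr et al. 2007,avialan,adult,0.27,0.57,humerus_Liu,Liu,0.19,0.05,36,False,True
Archaeopteryx lithographica,Thermopolis,Mayr et al. 2007,avialan,adult,0.27,0.57,humerus_Fe,Fe,0.27,0.05,51,False,True
Archaeopteryx lithographica,Eichstatt,Mayr et al. 2007,avialan,juvenile,0.19,0.39,humerus_Liu,Liu,0.11,0.02,47,True,True
Archaeopteryx lithographica,Eichstatt,Mayr et al. 2007,avialan,juvenile,0.19,0.39,humerus_Fe,Fe,0.14,0.02,60,True,True
Aurornis xui,YFGP-T5198,Godefroit et al. 2013,nonavian,adult,0.22,0.47,femur_CF,CF,0.38,0.02,160,True,True
Caudipteryx zoui,IVPP 12344,Zhou et al. 2000,nonavian,adult,0.35,0.72,femur_CF,CF,5.52,0.09,631,False,False
Caudipteryx sp.,IVPP 12430,Sullivan et al. 2014,nonavian,adult,0.28,0.58,femur_CF,CF,3.77,0.04,863,False,False
Changyuraptor yangi,HG B016,Han et al. 2014,nonavian,adult,0.68,1.42,femur_CF,CF,5.64,0.43,130,True,True
Citipati osmolskae,MPC-D100/971,Lu et al. 2013,nonavian,embryo,0.11,0.22,femur_CF,CF,0.05,0.0,397,True,False
Confuciusornis sanctus,,Chiappe et al. 1999,avialan,adult,0.32,0.67,humerus_Liu,Liu,0.14,0.09,15,False,True
Confuciusornis sanctus,,Chiappe et al. 1999,avialan,adult,0.32,0.67,humerus_Fe,Fe,0.19,0.09,20,False,True
Eoconfuciusornis zhengi,,Sullivan et al. 2014,avialan,adult,0.22,0.46,humerus_Liu,Liu,0.09,0.04,24,False,True
Eoconfuciusornis zhengi,,Sullivan et al. 2014,avialan,adult,0.22,0.46,humerus_Fe,Fe,0.12,0.04,30,False,True
Eosinopteryx brevipenna,YFGP-T5197,Godefroit et al. 2013,nonavian,adult,0.16,0.33,femur_CF,CF,0.14,0.01,111,False,True
Jeholornis prima,,Ji et al. 2002,avialan,adult,0.41,0.86,humerus_Liu,Liu,0.34,0.12,29,False,True
Jeholornis prima,,Ji et al. 2002,avialan,adult,0.41,0.86,humerus_Fe,Fe,0.54,0.12,45,False,True
Jeholornis sp.,,Zhou and Zhang 2003,avialan,adult,0.55,1.15,humerus_Liu,Liu,0.6,0.21,28,True,True
Jeholornis sp.,,Zhou and Zhang 2003,avialan,adult,0.55,1.15,humerus_Fe,Fe,1.05,0.21,49,True,True
Jianchangosaurus yixianensis,41HIII-0308A,Pu et al. 2013,nonavian,adult,0.4,0.83,femur_CF,CF,14.7,0.03,5018,True,False
Jinfengopteryx elegans,CAGS-IG 04-0801,Ji et al. 2005,nonavian,adult,0.17,0.37,femur_CF,CF,0.46,0.01,317,True,True
Mahakala omnogovae,IGM 100/1033,Turner et al. 2011,nonavian,adult,0.2,0.42,femur_CF,CF,0.67,0.03,229,True,True
Mei long,DNHM D2154,Gao et al. 2012,nonavian,adult,0.12,0.26,femur_CF,CF,0.36,0.01,505,True,True
Mei long,IVPP V12733,Xu and Norell 2004,nonavian,adult,0.15,0.31,femur_CF,CF,0.73,0.01,714,True,True
Microraptor gui,BMNHC PH 881,Li et al. 2012,nonavian,adult,0.24,0.5,femur_CF,CF,0.17,0.04,46,False,True
Microraptor gui,IVPP V 13352,Xu et al. 2003 and Sullivan et al. 2014,nonavian,adult,0.41,0.86,femur_CF,CF,0.88,0.12,69,False,True
Microraptor hanqingi,LVH 0026,Gong et al. 2012,nonavian,adult,0.47,0.98,femur_CF,CF,2.05,0.18,110,True,True
Oviraptor incertae sedis,MPC-D100/1018,Lu et al. 2013,nonavian,embryo,0.09,0.19,femur_CF,CF,0.03,0.0,305,True,False
Protarchaeopteryx robusta,GMV2125,Ji and Ji 1997,nonavian,adult,0.26,0.54,femur_CF,CF,2.58,0.02,1445,False,False
Sapeornis chaoyangensis,,Pu et al. 2013,avialan,adult,0.44,0.92,humerus_Liu,Liu,0.51,0.12,43,False,True
Sapeornis chaoyangensis,,Pu et al. 2013,avialan,adult,0.44,0.92,humerus_Fe,Fe,0.88,0.12,74,False,True
Sapeornis sp.,,Zhou and Zhang 2003b and Gao et al. 2012b,avialan,adult,0.57,1.21,humerus_Liu,Liu,0.8,0.2,40,True,True
Sapeornis sp.,,Zhou and Zhang 2003b and Gao et al. 2012b,avialan,adult,0.57,1.21,humerus_Fe,Fe,1.49,0.2,74,True,True
Similicaudipteryx yixianensis,STM22-6,Xu et al. 2010,nonavian,adult,0.4,0.84,femur_CF,CF,4.23,0.12,345,False,False
Similicaudipteryx yixianensis,STM4-1,Xu et al. 2010,nonavian,juvenile,0.07,0.15,femur_CF,CF,0.06,0.0,372,False,False
Sinocalliopteryx gigas,JMP-V-05-8-01,Sullivan et al. 2014,nonavian,adult,0.37,0.77,femur_CF,CF,18.43,0.05,3596,False,False
Sinornithoides youngi,IVPP V9612,Russell and Dong 1993,nonavian,adult,0.31,0.77,femur_CF,CF,18.4,0.04,1151,False,True
Sinornithosaurus millenii,NGMC-91A,Xu et al. 1999,nonavian,adult,0.26,0.54,femur_CF,CF,1.94,0.02,1032,False,True
Sinornithosaurus sp.,ref-151,Sullivan et al. 2014,nonavian,adult,0.19,0.41,femur_CF,CF,0.29,0.01,229,False,True
Sinosauropteryx prima,NICP 127587,Currie and Chen 2001,nonavian,adult,0.1,0.2,femur_CF,CF,0.88,0.0,4755,False,False
Sinosauropteryx prima,NIGP 127586,Currie and Chen 2001,nonavian,juvenile,0.05,0.09,femur_CF,CF,0.19,0.0,11910,False,False
Sinovenator changii,IVPP V11977,Xu et al. 2002,nonavian,adult,0.24,0.5,femur_CF,CF,2.44,0.03,919,True,True
Tianyuraptor ostromi,STM1-3,Zheng et al. 2010,nonavian,adult,0.39,0.82,femur_CF,CF,13.36,0.06,2272,False,True
Troodon formosus,MOR 246-1,Varricchio et al. 2002,nonavian,embryo,0.08,0.16,femur_CF,CF,0.05,0.0,214,True,True
Xiaotingia zhengi,STM 27-2,Xu et al. 2011,nonavian,adult,0.24,0.5,femur_CF,CF,0.82,0.03,305,True,True
Yixianosaurus longimanus,IVPP 12638,Xu and Wang 2003,nonavian,adult,0.29,0.61,literature,lit-low,1.3,0.04,323,False,False
Yixianosaurus longimanus,IVPP 12638,Xu and Wang 2003,nonavian,adult,0.29,0.61,literature,lit-high,1.89,0.04,470,False,False
Yulong mini,41HIII-0107,Lu et al. 2013,nonavian,juvenile,0.18,0.38,femur_CF,CF,0.5,0.02,280,True,False
Zhenyuanlong suni,JPM-0008,Lu and Brusatte 2015,nonavian,adult,0.58,1.22,femur_CF,CF,11.99,0.23,515,False,True
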