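taxon,specimen_label,mass_label,speed_m_s,bw_ALL,bw_GF,bw_MOD
Anchiornis huxleyi,BMNHC PH828,CF,1.5,0.24,0.22,0.22
Anchiornis huxleyi,BMNHC PH828,CF,0.6,0.17,0.15,0.15
Anchiornis huxleyi,LPM B00169,CF,1.5,0.10,0.09,0.12
Anchiornis huxleyi,LPM B00169,CF,0.6,0.06,0.06,0.08
Archaeopteryx lithographica,11th,Liu,1.5,0.70,0.62,0.78
Archaeopteryx lithographica,11th,Fe,1.5,0.37,0.33,0.46
Archaeopteryx lithographica,11th,Liu,0.6,0.52,0.45,0.59
Archaeopteryx lithographica,11th,Fe,0.6,0.27,0.23,0.34
Archaeopteryx lithographica,Berlin,Liu,1.5,0.67,0.60,0.74
Archaeopteryx lithographica,Berlin,Fe,1.5,0.38,0.34,0.46
Archaeopteryx lithographica,Berlin,Liu,0.6,0.50,0.43,0.56
Archaeopteryx lithographica,Berlin,Fe,0.6,0.27,0.24,0.34
Archaeopteryx lithographica,London,Liu,1.5,0.57,0.50,0.67
Archaeopteryx lithographica,London,Fe,1.5,0.28,0.25,0.37
Archaeopteryx lithographica,London,Liu,0.6,0.42,0.37,0.51
Archaeopteryx lithographica,London,Fe,0.6,0.20,0.17,0.27
Archaeopteryx lithographica,Munich,Liu,1.5,0.66,0.59,0.68
Archaeopteryx lithographica,Munich,Fe,1.5,0.39,0.34,0.43
Archaeopteryx lithographica,Munich,Liu,0.6,0.48,0.42,0.51
Archaeopteryx lithographica,Munich,Fe,0.6,0.28,0.24,0.32
Archaeopteryx lithographica,Thermopolis,Liu,1.5,0.71,0.63,0.75
Archaeopteryx lithographica,Thermopolis,Fe,1.5,0.41,0.37,0.47
Archaeopteryx lithographica,Thermopolis,Liu,0.6,0.52,0.46,0.56
Archaeopteryx lithographica,Thermopolis,Fe,0.6,0.29,0.26,0.34
Archaeopteryx lithographica,Eichstatt,Liu,1.5,0.42,0.38,0.39
Archaeopteryx lithographica,Eichstatt,Fe,1.5,0.29,0.26,0.28
Archaeopteryx lithographica,Eichstatt,Liu,0.6,0.30,0.26,0.27
Archaeopteryx lithographica,Eichstatt,Fe,0.6,0.20,0.17,0.19
Aurornis xui,YFGP-T5198,CF,1.5,0.08,0.07,0.10
Aurornis xui,YFGP-T5198,CF,0.6,0.05,0.05,0.07
Caudipteryx zoui,IVPP 12344,CF,1.5,0.01,0.01,0.02
Caudipteryx zoui,IVPP 12344,CF,0.6,0.01,0.00,0.01
Caudipteryx sp.,IVPP 12430,CF,1.5,0.01,0.01,0.01
Caudipteryx sp.,IVPP 12430,CF,0.6,0.00,0.00,0.01
Changyuraptor yangi,HG B016,CF,1.5,0.11,0.10,0.25
Changyuraptor yangi,HG B016,CF,0.6,0.05,0.05,0.14
Citipati osmolskae,MPC-D100/971,CF,1.5,0.03,0.03,0.03
Citipati osmolskae,MPC-D100/971,CF,0.6,0.02,0.02,0.02
Eosinopteryx brevipenna,YFGP-T5197,CF,1.5,0.12,0.11,0.12
Eosinopteryx brevipenna,YFGP-T5197,CF,0.6,0.08,0.07,0.08
Jianchangosaurus yixianensis,41HIII-0308A,CF,1.5,0.00,0.00,0.00
Jianchangosaurus yixianensis,41HIII-0308A,CF,0.6,0.00,0.00,0.00
Jinfengopteryx elegans,CAGS-IG 04-0801,CF,1.5,0.03,0.02,0.03
Jinfengopteryx elegans,CAGS-IG 04-0801,CF,0.6,0.02,0.01,0.02
Mahakala omnogovae,IGM 100/1033,CF,1.5,0.04,0.03,0.05
Mahakala omnogovae,IGM 100/1033,CF,0.6,0.02,0.02,0.03
Mei long,DNHM D2154,CF,1.5,0.01,0.01,0.02
Mei long,DNHM D2154,CF,0.6,0.01,0.01,0.01
Mei long,IVPP V12733,CF,1.5,0.01,0.01,0.01
Mei long,IVPP V12733,CF,0.6,0.00,0.00,0.01
Microraptor gui,BMNHC PH 881,CF,1.5,0.49,0.43,0.50
Microraptor gui,BMNHC PH 881,CF,0.6,0.35,0.31,0.36
Microraptor gui,IVPP V 13352,CF,1.5,0.28,0.25,0.42
Microraptor gui,IVPP V 13352,CF,0.6,0.20,0.17,0.32
Microraptor hanqingi,LVH 0026,CF,1.5,0.14,0.12,0.24
Microraptor hanqingi,LVH 0026,CF,0.6,0.08,0.07,0.15
Oviraptor incertae sedis,MPC-D100/1018,CF,1.5,0.05,0.04,0.03
Oviraptor incertae sedis,MPC-D100/1018,CF,0.6,0.03,0.03,0.02
Protarchaeopteryx robusta,GMV2125,CF,1.5,0.00,0.00,0.01
Protarchaeopteryx robusta,GMV2125,CF,0.6,0.00,0.00,0.00
Similicaudipteryx yixianensis,STM22-6,CF,1.5,0.02,0.02,0.05
Similicaudipteryx yixianensis,STM22-6,CF,0.6,0.01,0.01,0.03
Similicaudipteryx yixianensis,STM4-1,CF,1.5,0.02,0.02,0.02
Similicaudipteryx yixianensis,STM4-1,CF,0.6,0.01,0.01,0.01
Sinocalliopteryx gigas,JMP-V-05-8-01,CF,1.5,0.00,0.00,0.00
Sinocalliopteryx gigas,JMP-V-05-8-01,CF,0.6,0.00,0.00,0.00
Sinornithoides youngi,IVPP V9612,CF,1.5,0.01,0.01,0.01
Sinornithoides youngi,IVPP V9612,CF,0.6,0.00,0.00,0.01
Sinornithosaurus millenii,NGMC-91A,CF,1.5,0.01,0.01,0.01
Sinornithosaurus millenii,NGMC-91A,CF,0.6,0.00,0.00,0.01
Sinornithosaurus sp.,ref-151,CF,1.5,0.05,0.05,0.06
Sinornithosaurus sp.,ref-151,CF,0.6,0.03,0.03,0.04
Sinosauropteryx prima,NICP 127587,CF,1.5,0.00,0.00,0.00
Sinosauropteryx prima,NICP 127587,CF,0.6,0.00,0.00,0.00
Sinosauropteryx prima,NIGP 127586,CF,1.5,0.00,0.00,0.00
Sinosauropteryx prima,NIGP 127586,CF,0.6,0.00,0.00,0.00
Sinovenator changii,IVPP V11977,CF,1.5,0.01,0.01,0.01
Sinovenator changii,IVPP V11977,CF,0.6,0.00,0.00,0.01
Tianyuraptor ostromi,STM1-3,CF,1.5,0.00,0.00,0.00
Tianyuraptor ostromi,STM1-3,CF,0.6,0.00,0.00,0.00
Troodon formosus,MOR 246-1,CF,1.5,0.04,0.04,0.03
Troodon formosus,MOR 246-1,CF,0.6,0.02,0.02,0.02
Xiaotingia zhengi,STM 27-2,CF,1.5,0.03,0.03,0.05
Xiaotingia zhengi,STM 27-2,CF,0.6,0.02,0.02,0.03
Yixianosaurus longimanus,IVPP 12638,lit-low,1.5,0.03,0.03,0.05
Yixianosaurus longimanus,IVPP 12638,lit-high,1.5,0.02,0.02,0.03
Yixianosaurus longimanus,IVPP 12638,lit-low,0.6,0.02,0.02,0.03
Yixianosaurus longimanus,IVPP 12638,lit-high,0.6,0.01,0.01,0.02
Yulong mini,41HIII-0107,CF,1.5,0.03,0.03,0.04
Yulong mini,41HIII-0107,CF,0.6,0.02,0.02,0.02
Zhenyuanlong suni,JPM-0008,CF,1.5,0.02,0.01,0.04
Zhenyuanlong suni,JPM-0008,CF,0.6,0.01,0.01,0.03
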