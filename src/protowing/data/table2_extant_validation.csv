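taxon,stage,mass_lo_kg,mass_hi_kg,area_m2,flap_angle_rad,freq_lo_hz,freq_hi_hz,speed_m_s,bw_cl10_lo,bw_cl10_hi,bw_cl12_lo,bw_cl12_hi,bw_cl15_lo,bw_cl15_hi,bw_cl16_lo,bw_cl16_hi
Chukar,I,0.024,0.024,0.0036,1.57,22,22,0.60,0.06,0.06,0.08,0.08,,,,
Chukar,II,0.222,0.222,0.0297,2.5,18.7,18.7,1.20,0.85,0.85,1.02,1.02,,,,
Chukar,III,0.605,0.605,0.0499,2.16,18.7,18.7,1.50,0.65,0.65,0.78,0.78,0.97,0.97,1.02,1.02
Pigeon,WAIR 65,0.42,0.47,0.067,1.57,6.2,6.7,1.50,0.21,0.26,0.25,0.31,0.31,0.39,0.33,0.41
Pigeon,WAIR 85,0.42,0.47,0.067,1.57,7.3,7.7,1.50,0.28,0.31,0.34,0.37,0.42,0.46,0.45,0.49
Northern bobwhite,Take off,0.199,0.199,0.0243,2.44,19.9,19.9,3.25,,,,,,,1.25,1.25
Chukar,Take off,0.4915,0.4915,0.0483,2.64,16.1,16.1,2.87,,,,,,,1.62,1.62
Ring necked pheasant,Take off,0.9434,0.9434,0.1002,2.64,11,11,2.34,,,,,,,1.37,1.37
Turkey,Take off,5.275,5.275,0.3453,2.79,7.6,7.6,2.32,,,,,,,1.26,1.26
Blue breasted quail,Take off,0.0436,0.0436,0.0098,2.44,23.2,23.2,4.81,,,,,,,2.42,2.42
Harris hawk,Take off,0.92,0.92,0.119,2.60,5.8,5.8,4.13,,,,,,,2.07,2.07
Pigeon,Take off,0.307,0.307,0.0352,2.48,9.1,9.1,2.62,,,,,,,1.19,1.19
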