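tg,cn,db,ecn,rrt,rrf,recovery_pct,lod_ug_ml,loq_ug_ml,precision_pct,repeatability_pct,rsd_pct
LLL,54,6,42,0.97,0.44,21,0.001,0.001,2.8,8.0,1.80
LLO,54,5,44,0.95,1.47,148,0.083,0.251,20.0,52.6,3.53
LOL,54,5,44,0.95,0.73,74,0.169,0.511,7.0,19.5,2.63
OOLn,54,5,44,0.96,0.42,36,0.330,1.000,17.7,49.6,11.74
OOL,54,4,46,0.94,1.11,56,0.109,0.330,18.0,50.3,4.46
LLS,54,4,46,0.95,0.85,41,0.140,0.424,2.26,6.3,0.73
PPL,50,2,46,0.79,1.11,73,0.125,0.379,7.3,20.7,1.84
PPP,48,0,48,0.70,0.86,79,0.140,0.421,2.2,6.3,0.73
OOP,52,2,48,0.85,1.39,140,0.088,0.267,0.3,0.7,3.64
OPO,52,2,48,0.86,1.24,125,0.181,0.549,0.5,1.5,2.87
OOO,54,3,48,0.93,2.28,102,0.053,0.16,26.7,74.8,3.23
PPS,50,0,50,0.77,1.72,108,0.001,0.001,20.7,57.9,3.33
PSO,52,1,50,0.85,1.52,74,0.170,0.515,22.6,63.4,4.11
OOS,54,2,50,0.92,1.72,99,0.067,0.202,0.2,0.6,0.57
SSO,54,1,52,0.91,1.00,61,0.001,0.001,8.2,23.0,2.27
SSS,54,0,54,0.91,1.00,90,0.010,0.010,2.1,20.1,1.92
NNN,57,0,57,1.00,1.00,100,0.117,0.354,16.1,45.1,4.45
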