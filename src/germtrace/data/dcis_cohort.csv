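patient_id,bcse,race,ethnicity,age_range,surgery,size_cm,grade,er_status,days
OXPA003,Yes,White,Non-Hispanic,41-50,Lumpectomy,0.8,1,+,2554
OXPA028,Yes,White,Non-Hispanic,51-60,Mastectomy,0.5,1,+,1012
OXPA033,Yes,White,Non-Hispanic,71-80,Lumpectomy,NA,1,+,1024
OXPA036,Yes,White,Non-Hispanic,51-60,Lumpectomy,NA,1,+,2296
OXPA161,Yes,White,Non-Hispanic,61-70,Mastectomy,0.4,1,+,3752
OXPA166,Yes,White,Non-Hispanic,51-60,Lumpectomy,0.7,1,+,7037
OXPA020,Yes,White,Non-Hispanic,51-60,Lumpectomy,NA,1,NA,5967
OXPA021,Yes,White,Non-Hispanic,41-50,Lumpectomy,0.9,1,NA,2398
OXPA527,Yes,White,Hispanic,41-50,Lumpectomy,0.7,1,NA,2203
OXPA002,Yes,Asian,Non-Hispanic,41-50,Lumpectomy,1.4,2,+,2492
OXPA006,Yes,White,Non-Hispanic,61-70,Lumpectomy,1,2,+,3022
OXPA032,Yes,Asian,Non-Hispanic,41-50,Lumpectomy,2.5,2,+,502
OXPA044,Yes,White,Non-Hispanic,51-60,Lumpectomy,0.9,2,+,2147
OXPA064,Yes,White,Non-Hispanic,71-80,Lumpectomy,0.4,2,+,553
OXPA179,Yes,White,Hispanic,71-80,Lumpectomy,1.2,2,NA,3077
OXPA147,Yes,White,Non-Hispanic,61-70,Lumpectomy,1.1,3,+,1981
OXPA185,Yes,White,Non-Hispanic,41-50,Lumpectomy,0.3,3,+,497
OXPA150,Yes,White,Non-Hispanic,51-60,Lumpectomy,0.4,NA,+,2402
OXPA153,Yes,White,Non-Hispanic,61-70,Lumpectomy,0.5,NA,+,3970
OXPA246,Yes,White,Non-Hispanic,71-80,Lumpectomy,0.5,NA,+,1179
OXPA267,Yes,White,Non-Hispanic,61-70,Mastectomy,NA,NA,+,3083
OXPA151,Yes,White,Non-Hispanic,71-80,Lumpectomy,NA,NA,NA,1029
OXPA644,No,White,Non-Hispanic,51-60,Lumpectomy,1.1,1,-,2456
OXPA347,No,White,Non-Hispanic,81-90,Lumpectomy,5,1,+,3894
OXPA508,No,White,Non-Hispanic,51-60,Lumpectomy,0.9,1,+,2570
OXPA172,No,White,Non-Hispanic,71-80,Lumpectomy,1.8,1,NA,6903
OXPA295,No,White,Non-Hispanic,51-60,Lumpectomy,1.2,1,NA,4903
OXPA092,No,White,Non-Hispanic,51-60,Lumpectomy,0.5,2,+,3822
OXPA156,No,White,Hispanic,41-50,Lumpectomy,0.5,2,+,7170
OXPA392,No,White,Non-Hispanic,51-60,Lumpectomy,0.6,2,+,3709
OXPA445,No,White,Non-Hispanic,51-60,Lumpectomy,1.3,2,+,3594
OXPA501,No,Asian,Non-Hispanic,41-50,Lumpectomy,1.2,2,+,3044
OXPA530,No,White,Hispanic,61-70,Lumpectomy,1.5,2,+,3167
OXPA540,No,Asian,Non-Hispanic,41-50,Lumpectomy,1.8,2,+,2941
OXPA182,No,White,Non-Hispanic,51-60,Lumpectomy,0.5,3,NA,4543
OXPA146,No,White,Non-Hispanic,41-50,Lumpectomy,1,NA,+,7067
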