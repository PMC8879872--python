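patient_id,lesion_index,total_dose_gy,n_fractions,treatment_days,followup_days,v_pre_cm3,v_post_cm3,not_measurable,in_regimen_stats,mld_gy,tlv_cm3,v5_pct,v20_pct
001,1,54,3,1-3-6,191,0.6,0.2,false,true,1.2,4870.8,6.1,0.9
002,1,48,4,1-3-5-8,63,0.9,0,false,true,2.7,2653.7,13,2.8
003,1,54,3,1-3-6,123,1,0.5,false,true,2.4,3758.1,12,1.7
005,1,54,3,1-3-6,126,0.4,0,true,true,1.1,5031.4,5,0.9
006,1,48,4,1-3-5-8,124,4.2,1.4,false,true,2.1,5263.3,1.6,2.1
008,1,48,4,1-3-6-8,109,18,1.5,false,true,3.4,3598.8,13.9,4.5
009,1,54,3,1-3-6,90,5.7,3.3,false,true,2.5,5485.3,12.4,3
010,1,48,4,1-3-6-9,169,4.3,2,false,true,1.9,3932.6,8.6,2
011,1,48,4,1-3-6-8,172,5.4,2.8,false,true,5.3,3340.5,34.3,4.3
012,1,54,3,1-4-6,98,1.2,1.6,false,true,7.3,2335,31.5,13
012,2,54,3,3-5-7,98,0.9,0,false,true,7.3,2335,31.5,13
012,3,54,3,3-5-7,98,0.9,0.3,false,false,7.3,2335,31.5,13
013,1,48,4,2-6-8-10,125,0.9,0.4,false,true,5,2886.4,28,4.8
013,2,48,4,1-3-7-9,125,5.6,4.6,false,true,5,2886.4,28,4.8
014,1,54,3,1-3-6,150,2.6,0,true,true,3.7,2229,15.1,6
015,1,60,8,1-3-6-8-10-13-15-17,112,10.5,11,false,true,4.5,3307.4,17,6.3
016,1,48,4,1-3-7-10,124,20,2.8,false,true,3.7,4477,17.5,4
018,1,54,3,1-3-7,115,1.5,0.3,false,true,1,4463.8,4.5,1.3
019,1,34,1,1,103,0.3,0.2,false,true,1.2,3336.3,5.9,0.7
020,1,48,4,1,145,0.6,0.6,false,false,1.7,2602.2,7.6,1.7
020,2,34,1,2-4-7-9,145,1.1,0,false,true,1.7,2602.2,7.6,1.7
021,1,48,4,1-3-8-11,133,0.6,0,true,true,1.9,2392.4,9.6,1.6
022,1,54,3,1-2-6,123,2.1,0,true,true,3.2,2830,16.5,3.4
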