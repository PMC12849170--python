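group_id,range_start,range_end
g_diarrhoeal,A00,A09
g_tuberculosis,A15,A19
g_bacterial_other,A20,A99
g_viral,B00,B49
g_malaria,B50,B54
g_parasitic_other,B55,B99
g_cancers,C00,C97
g_neoplasm_other,D00,D48
g_anaemia,D50,D64
g_blood_immune,D65,D89
g_thyroid,E00,E07
g_diabetes,E10,E14
g_endocrine_other,E15,E35
g_malnutrition,E40,E46
g_deficiency_other,E50,E64
g_metabolic_other,E65,E90
g_mental_organic,F00,F09
g_substance,F10,F19
g_mental_other,F20,F99
g_neuro_infl,G00,G39
g_epilepsy,G40,G41
g_neuro_other,G42,G99
g_sense_organs,H00,H95
g_cvd_hypertensive,I00,I15
g_ihd,I20,I25
g_cardiac_other,I26,I52
g_stroke,I60,I69
g_vascular_other,I70,I99
g_resp_upper,J00,J08
g_pneumonia_flu,J09,J22
g_resp_upper_chronic,J30,J39
g_copd,J40,J44
g_asthma,J45,J46
g_resp_chronic_other,J47,J98
g_digestive_upper,K00,K69
g_liver,K70,K77
g_digestive_other,K80,K93
g_skin_musculo,L00,M99
g_genitourinary,N00,N99
g_maternal_early,O00,O48
g_maternal_late,O60,O99
g_perinatal_maternal,P00,P04
g_prematurity,P05,P07
g_postmaturity,P08,P09
g_birth_trauma,P10,P15
g_asphyxia,P20,P21
g_resp_newborn,P22,P29
g_neonatal_infections,P35,P39
g_perinatal_misc,P50,P94
g_stillbirth,P95,P95
g_perinatal_term,P96,P96
g_congenital,Q00,Q99
g_ill_defined,R00,R99
g_road_transport,V01,V99
g_falls_drowning,W00,W99
g_fire_poison_exposure,X00,X59
g_suicide,X60,X84
g_homicide,X85,Y09
g_injury_undetermined,Y10,Y98
g_special_unmapped,U60,U69
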