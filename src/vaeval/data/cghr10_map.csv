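source_system,range_start,range_end,age_stratum,target_id
ICD10,A00,A09,adult,diarrhoeal
ICD10,A15,A19,adult,tuberculosis
ICD10,A20,A99,adult,other_infections
ICD10,B00,B49,adult,other_infections
ICD10,B50,B54,adult,malaria
ICD10,B55,B99,adult,other_infections
ICD10,C00,C97,adult,cancers
ICD10,D00,D48,adult,cancers
ICD10,D50,D64,adult,anaemia_nutritional
ICD10,D65,D89,adult,other_ncd
ICD10,E00,E07,adult,other_ncd
ICD10,E10,E14,adult,diabetes
ICD10,E15,E35,adult,other_ncd
ICD10,E40,E46,adult,anaemia_nutritional
ICD10,E50,E90,adult,other_ncd
ICD10,F00,F09,adult,other_ncd
ICD10,F10,F19,adult,liver_alcohol
ICD10,F20,H95,adult,other_ncd
ICD10,I00,I59,adult,ischemic_heart
ICD10,I60,I69,adult,stroke
ICD10,I70,I99,adult,ischemic_heart
ICD10,J00,J08,adult,other_infections
ICD10,J09,J22,adult,pneumonia
ICD10,J30,J98,adult,chronic_respiratory
ICD10,K00,K69,adult,other_ncd
ICD10,K70,K77,adult,liver_alcohol
ICD10,K80,K93,adult,other_ncd
ICD10,L00,N99,adult,other_ncd
ICD10,O00,O99,adult,maternal
ICD10,R00,R99,adult,ill_defined
ICD10,V01,V99,adult,road_transport
ICD10,W00,X59,adult,other_injuries
ICD10,X60,X84,adult,suicide
ICD10,X85,Y09,adult,homicide
ICD10,Y10,Y98,adult,other_injuries
ICD10,A00,A09,child,diarrhoeal
ICD10,A10,A99,child,other_infections
ICD10,B00,B49,child,other_infections
ICD10,B50,B54,child,malaria
ICD10,B55,B99,child,other_infections
ICD10,C00,D48,child,other_ncd
ICD10,D50,D64,child,nutritional
ICD10,D65,D89,child,other_ncd
ICD10,E00,E35,child,other_ncd
ICD10,E40,E64,child,nutritional
ICD10,E65,E90,child,other_ncd
ICD10,F00,G39,child,other_ncd
ICD10,G40,G41,child,epilepsy
ICD10,G42,H95,child,other_ncd
ICD10,I00,I99,child,other_ncd
ICD10,J00,J08,child,other_infections
ICD10,J09,J22,child,pneumonia
ICD10,J30,J98,child,other_ncd
ICD10,K00,N99,child,other_ncd
ICD10,Q00,Q99,child,congenital
ICD10,R00,R99,child,ill_defined
ICD10,V01,Y98,child,injuries
ICD10,A00,B99,neonate,neonatal_infections
ICD10,P00,P04,neonate,other_neonatal
ICD10,P05,P07,neonate,prematurity_lbw
ICD10,P08,P09,neonate,other_neonatal
ICD10,P10,P29,neonate,birth_asphyxia_trauma
ICD10,P35,P39,neonate,neonatal_infections
ICD10,P50,P94,neonate,other_neonatal
ICD10,P95,P95,neonate,stillbirth
ICD10,P96,P96,neonate,other_neonatal
ICD10,Q00,Q99,neonate,congenital
ICD10,R00,R99,neonate,ill_defined
WHOVA2016,01.01,01.01,adult,other_infections
WHOVA2016,01.02,01.02,adult,pneumonia
WHOVA2016,01.04,01.04,adult,diarrhoeal
WHOVA2016,01.05,01.05,adult,malaria
WHOVA2016,01.09,01.09,adult,tuberculosis
WHOVA2016,01.02,01.02,child,pneumonia
WHOVA2016,01.04,01.04,child,diarrhoeal
WHOVA2016,01.05,01.05,child,malaria
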