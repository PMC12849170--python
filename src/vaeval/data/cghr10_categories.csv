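stratum,id,label
adult,diarrhoeal,Diarrhoeal diseases
adult,tuberculosis,Tuberculosis
adult,other_infections,Unspecified and other infections
adult,malaria,Malaria
adult,cancers,Cancers
adult,anaemia_nutritional,Anaemia and nutritional deficiencies
adult,diabetes,Diabetes mellitus
adult,other_ncd,Other non-communicable diseases
adult,ischemic_heart,Ischaemic heart and other vascular diseases
adult,stroke,Stroke
adult,pneumonia,Pneumonia
adult,chronic_respiratory,Asthma and chronic respiratory diseases
adult,liver_alcohol,Liver and alcohol-related diseases
adult,maternal,Maternal conditions
adult,ill_defined,Ill-defined causes
adult,road_transport,Road and transport injuries
adult,other_injuries,Other injuries
adult,suicide,Suicide
adult,homicide,Homicide and violence
child,diarrhoeal,Diarrhoeal diseases
child,other_infections,Other infections
child,malaria,Malaria
child,pneumonia,Pneumonia
child,nutritional,Nutritional deficiencies
child,other_ncd,Other non-communicable diseases
child,epilepsy,Epilepsy
child,congenital,Congenital anomalies
child,ill_defined,Ill-defined causes
child,injuries,Injuries
neonate,birth_asphyxia_trauma,Birth asphyxia and birth trauma
neonate,prematurity_lbw,Prematurity and low birthweight
neonate,neonatal_infections,Neonatal infections
neonate,stillbirth,Stillbirth
neonate,congenital,Congenital anomalies
neonate,ill_defined,Ill-defined causes
neonate,other_neonatal,Other neonatal causes
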