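cause,prior,fever,cough,breathless,chest_pain,loose_stools,vomiting,abdominal_pain,headache,stiff_neck,rash,weight_loss,night_sweats,swelling,jaundice,convulsions,unconscious,pallor,injury_event,pregnancy_related,birth_complication
birth_asphyxia_trauma,0.090222,0.060649,0.049161,0.043661,0.131823,0.131481,0.033463,0.775028,0.678346,0.111168,0.077028,0.082583,0.116198,0.077065,0.144783,0.060230,0.034535,0.052921,0.027263,0.139875,0.802184
prematurity_lbw,0.111723,0.045521,0.024778,0.130089,0.068239,0.047210,0.072855,0.041174,0.029297,0.705393,0.021111,0.100357,0.062887,0.053367,0.079714,0.855452,0.051420,0.036695,0.838501,0.056410,0.130056
neonatal_infections,0.205506,0.686047,0.147750,0.043569,0.036376,0.040605,0.146967,0.871851,0.097704,0.064469,0.039633,0.022539,0.124217,0.080672,0.148583,0.790749,0.131042,0.041374,0.148336,0.039660,0.049447
stillbirth,0.017619,0.080400,0.087546,0.041305,0.114141,0.745257,0.030225,0.748096,0.119758,0.027812,0.108270,0.750628,0.136637,0.090285,0.068117,0.032097,0.054879,0.039868,0.086943,0.023399,0.118429
congenital,0.100652,0.148818,0.038924,0.104778,0.136284,0.048944,0.738663,0.114313,0.118386,0.053152,0.709608,0.123141,0.136584,0.093443,0.032795,0.103739,0.656725,0.134381,0.065242,0.099001,0.090448
ill_defined,0.251622,0.036611,0.115090,0.879715,0.088802,0.075850,0.023772,0.035047,0.086334,0.073789,0.841408,0.048225,0.094437,0.077386,0.086277,0.100165,0.147049,0.113223,0.100601,0.677856,0.054843
other_neonatal,0.222655,0.118445,0.052934,0.106952,0.048884,0.124456,0.065408,0.138999,0.123746,0.142242,0.119549,0.067262,0.695589,0.793551,0.026734,0.144644,0.040901,0.633345,0.086847,0.109975,0.038957
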