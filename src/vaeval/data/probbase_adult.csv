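cause,prior,fever,cough,breathless,chest_pain,loose_stools,vomiting,abdominal_pain,headache,stiff_neck,rash,weight_loss,night_sweats,swelling,jaundice,convulsions,unconscious,pallor,injury_event,pregnancy_related,birth_complication
diarrhoeal,0.074023,0.142659,0.066725,0.122025,0.612887,0.058263,0.139954,0.822370,0.067338,0.146513,0.049188,0.124714,0.108517,0.750243,0.024005,0.136324,0.094572,0.070740,0.066108,0.104756,0.065114
tuberculosis,0.005771,0.613066,0.068222,0.027176,0.779101,0.129325,0.126360,0.106752,0.081176,0.146080,0.129234,0.051859,0.093781,0.144274,0.852663,0.068016,0.081090,0.087317,0.137246,0.112858,0.071758
other_infections,0.014738,0.080065,0.032000,0.083965,0.049773,0.032107,0.031866,0.048057,0.110886,0.043294,0.093890,0.098340,0.145615,0.079566,0.679293,0.024536,0.866740,0.813201,0.026160,0.137994,0.040251
malaria,0.020186,0.107782,0.652131,0.027991,0.037511,0.137172,0.121776,0.639139,0.785194,0.058189,0.088654,0.082643,0.143645,0.079047,0.117100,0.066625,0.140305,0.130808,0.148945,0.049516,0.133150
cancers,0.145118,0.082009,0.086220,0.090434,0.605037,0.768641,0.098571,0.033690,0.116077,0.034747,0.660028,0.107038,0.080484,0.028446,0.100894,0.067675,0.069574,0.041184,0.043909,0.149102,0.098578
anaemia_nutritional,0.026520,0.096365,0.121527,0.069860,0.040041,0.805918,0.072629,0.072449,0.031418,0.074718,0.026752,0.137254,0.068730,0.112991,0.096483,0.657827,0.063999,0.024152,0.105097,0.032929,0.611397
diabetes,0.059922,0.830717,0.068859,0.067125,0.856400,0.055067,0.067865,0.059972,0.110392,0.030047,0.069518,0.149644,0.768022,0.081770,0.057595,0.022948,0.138234,0.139704,0.147207,0.082332,0.097128
other_ncd,0.035357,0.057570,0.755523,0.095745,0.841333,0.058358,0.066310,0.107190,0.120044,0.033485,0.140755,0.117907,0.124634,0.045680,0.038574,0.671810,0.142065,0.065075,0.033000,0.062451,0.128907
ischemic_heart,0.019283,0.127088,0.050466,0.040136,0.084413,0.061669,0.130586,0.080447,0.049480,0.075961,0.856102,0.111506,0.766941,0.099098,0.050884,0.125567,0.857845,0.031460,0.039983,0.068215,0.128531
stroke,0.052807,0.049466,0.121723,0.705230,0.129152,0.620864,0.031475,0.720313,0.052691,0.043300,0.104158,0.081235,0.094498,0.057074,0.147188,0.033276,0.106182,0.089097,0.148684,0.144131,0.082351
pneumonia,0.030815,0.078241,0.619403,0.042340,0.807270,0.135290,0.081906,0.139289,0.051869,0.054721,0.144168,0.139528,0.086610,0.091602,0.065917,0.700407,0.068728,0.148062,0.086062,0.124933,0.040916
chronic_respiratory,0.061841,0.115441,0.096738,0.148266,0.060541,0.080648,0.055305,0.115859,0.792794,0.115071,0.128474,0.052256,0.891245,0.064916,0.772639,0.040262,0.138861,0.032038,0.024820,0.125533,0.028496
liver_alcohol,0.052714,0.093861,0.087320,0.135155,0.793239,0.147673,0.108599,0.063457,0.141865,0.030281,0.108687,0.034070,0.698686,0.070221,0.084958,0.026966,0.072741,0.089809,0.056260,0.813462,0.121339
maternal,0.113291,0.044762,0.060170,0.055892,0.052362,0.024845,0.898384,0.086119,0.062509,0.134462,0.022851,0.033778,0.022441,0.023977,0.020343,0.099111,0.113283,0.066034,0.140640,0.809099,0.849238
ill_defined,0.104111,0.119877,0.697430,0.027292,0.035566,0.062483,0.037676,0.102868,0.029035,0.090518,0.765337,0.069906,0.030275,0.113472,0.119323,0.061477,0.068927,0.110013,0.755858,0.099894,0.064473
road_transport,0.070042,0.111058,0.102616,0.060533,0.637519,0.070947,0.058474,0.118664,0.699878,0.084413,0.050801,0.084017,0.118340,0.090920,0.022018,0.031389,0.069981,0.648342,0.075591,0.101061,0.093368
other_injuries,0.035954,0.030517,0.082085,0.076113,0.079535,0.138394,0.834768,0.147069,0.081363,0.082103,0.112606,0.082023,0.027692,0.093083,0.031269,0.140812,0.876933,0.780273,0.087418,0.121571,0.085833
suicide,0.043671,0.047387,0.149620,0.102469,0.078575,0.142232,0.092339,0.669030,0.045825,0.063382,0.125507,0.040999,0.080175,0.103562,0.647757,0.071862,0.773824,0.126043,0.029614,0.076257,0.030959
homicide,0.033835,0.060830,0.121511,0.140257,0.025221,0.059153,0.109519,0.685547,0.148335,0.038476,0.620644,0.114653,0.110251,0.141787,0.653491,0.022150,0.036681,0.139861,0.076413,0.075771,0.055074
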