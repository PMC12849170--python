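cause,prior,fever,cough,breathless,chest_pain,loose_stools,vomiting,abdominal_pain,headache,stiff_neck,rash,weight_loss,night_sweats,swelling,jaundice,convulsions,unconscious,pallor,injury_event,pregnancy_related,birth_complication
diarrhoeal,0.022162,0.040799,0.603486,0.127099,0.058644,0.109037,0.890559,0.135876,0.093434,0.149115,0.051528,0.034209,0.064921,0.121298,0.090155,0.140153,0.149268,0.139892,0.041100,0.096709,0.803477
other_infections,0.067030,0.139466,0.039033,0.099640,0.027034,0.116605,0.649621,0.036460,0.034778,0.875719,0.084221,0.731503,0.147021,0.147223,0.058435,0.029728,0.057947,0.125756,0.054299,0.038495,0.098508
malaria,0.132467,0.109806,0.749845,0.681465,0.041293,0.050725,0.066971,0.093121,0.138725,0.065402,0.734767,0.106176,0.056752,0.092035,0.147757,0.149583,0.075205,0.127153,0.063438,0.124418,0.069116
pneumonia,0.072687,0.121256,0.030166,0.674846,0.101704,0.048314,0.058801,0.107833,0.058364,0.061433,0.126612,0.035305,0.025071,0.127960,0.137185,0.864648,0.101482,0.135853,0.088996,0.747438,0.068831
nutritional,0.083942,0.077293,0.130583,0.099429,0.028465,0.105666,0.129373,0.030809,0.648234,0.028317,0.110021,0.067677,0.651331,0.042814,0.042491,0.056900,0.123729,0.128713,0.122868,0.704751,0.064275
other_ncd,0.219730,0.078008,0.040326,0.897860,0.091196,0.058167,0.041617,0.031448,0.078996,0.088848,0.059817,0.021093,0.081328,0.144006,0.095303,0.082272,0.810519,0.062986,0.097038,0.751488,0.136021
epilepsy,0.192090,0.078993,0.106582,0.028263,0.067620,0.039631,0.044161,0.103263,0.105619,0.630014,0.062547,0.131131,0.121299,0.097579,0.068775,0.115952,0.615429,0.050459,0.023811,0.116528,0.890950
congenital,0.050733,0.733001,0.082488,0.081965,0.124029,0.037241,0.101042,0.087865,0.049166,0.060388,0.071018,0.035644,0.026525,0.040180,0.791822,0.131243,0.789870,0.126636,0.134366,0.049291,0.126914
ill_defined,0.109196,0.080773,0.864950,0.121134,0.083580,0.103232,0.038994,0.028128,0.129712,0.088797,0.026510,0.759496,0.118691,0.052980,0.111459,0.144805,0.096091,0.133865,0.861180,0.031751,0.067549
injuries,0.049963,0.037092,0.149164,0.041961,0.084469,0.029770,0.025536,0.837728,0.106696,0.070753,0.127823,0.114647,0.088034,0.120035,0.881263,0.030811,0.052572,0.089635,0.843250,0.092690,0.106334
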