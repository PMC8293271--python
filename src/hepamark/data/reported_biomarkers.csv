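trait,metabolite,class,bucket_bh_p2,bucket_important_peaks,bucket_total_peaks,bucket_corr,metab_vip,metab_bh_p,metab_corr
LW,Glucose-6-phosphate,carbohydrate,0.237,7,10,,,,
LW,Glucuronic acid,carbohydrate,<0.001,6,8,-0.93,,,
LW,Glyceric acid,carbohydrate,<0.001,2,2,-0.89,,,
LW,Glycogen,carbohydrate,0.070,2,2,-0.97,,,
LW,Lactate,carbohydrate,<0.001,2,2,0.98,4.11,<0.001,0.94
LW,Malic acid,carbohydrate,<0.001,2,4,-0.61,,,
LW,Maltose,carbohydrate,<0.001,12,13,-0.97,,,
LW,Arginine,amino acid,0.004,2,4,-0.92,,,
LW,N-acetylglycine,amino acid,0.141,1,2,,,,
LW,Proline,amino acid,0.237,3,5,,,,
LW,Taurine,amino acid,<0.001,2,2,-0.78,1.29,<0.001,-0.84
LW,trans-4-hydroxy-L-proline,amino acid,0.005,6,7,-0.81,,,
LW,Allantoin,organic compound,0.020,1,1,-0.80,,,
LW,Glycerophosphocholine,organic compound,0.070,3,4,-0.84,,,
LW,Glucose,carbohydrate,,,,,2.87,<0.001,-0.95
LW,Threonine,amino acid,,,,,1.72,<0.001,0.96
LW,Alanine,amino acid,,,,,1.55,<0.001,-0.90
TY,Glucose,carbohydrate,<0.001,21,22,0.92,2.80,<0.001,0.94
TY,Glucose-6-phosphate,carbohydrate,0.490,8,10,,,,
TY,Glyceric acid,carbohydrate,<0.001,2,2,0.90,,,
TY,Glycogen,carbohydrate,0.011,2,2,0.98,,,
TY,Lactate,carbohydrate,<0.001,2,2,-0.98,4.06,<0.001,-0.97
TY,Maltose,carbohydrate,<0.001,12,13,0.90,,,
TY,Arginine,amino acid,0.490,3,4,,,,
TY,Glutamic acid,amino acid,0.010,8,9,0.93,,,
TY,N-acetylglycine,amino acid,0.495,1,2,,,,
TY,Proline,amino acid,0.286,5,5,,,,
TY,trans-4-hydroxy-L-proline,amino acid,0.147,7,7,,,,
TY,Allantoin,organic compound,0.004,1,1,0.75,,,
TY,Creatine,organic compound,<0.001,2,2,-0.57,,,
TY,Ethanolamine,organic compound,0.009,2,2,0.95,,,
TY,Alanine,amino acid,,,,,1.43,<0.001,0.81
TY,Taurine,amino acid,,,,,1.51,<0.001,0.82
TY,Threonine,amino acid,,,,,1.72,<0.001,-0.95
TY,Guanidinoacetic acid,amino acid,,,,,1.04,<0.001,0.86
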