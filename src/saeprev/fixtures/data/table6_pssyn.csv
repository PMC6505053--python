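area_id,est_total,lo_total,hi_total,mse_total,est_male,lo_male,hi_male,mse_male,est_female,lo_female,hi_female,mse_female
A-gharbi,0.235,0.194,0.275,0.00043,0.205,0.198,0.212,1e-05,0.265,0.076,0.454,0.0093
A-sharghi,0.237,0.195,0.278,0.00044,0.208,0.127,0.29,0.00174,0.267,0.184,0.349,0.00177
Alborz,0.242,0.186,0.298,0.00081,0.217,-0.032,0.467,0.01624,0.267,0.206,0.329,0.00098
Ardebil,0.236,0.155,0.317,0.00171,0.205,0.183,0.227,0.00013,0.266,0.149,0.383,0.00357
Booshehr,0.236,0.13,0.342,0.00294,0.21,0.112,0.309,0.00253,0.265,0.148,0.383,0.00357
Chaharmahal-va-bakhtiari,0.234,0.054,0.414,0.00841,0.204,0.048,0.36,0.00634,0.265,0.112,0.417,0.00608
Fars,0.238,0.117,0.36,0.00385,0.211,0.05,0.372,0.00671,0.266,0.061,0.47,0.01089
Ghazvin,0.237,0.097,0.378,0.00514,0.209,-0.012,0.429,0.01268,0.266,0.006,0.527,0.01768
Ghom,0.241,0.143,0.339,0.00249,0.216,0.099,0.332,0.00355,0.267,0.239,0.295,0.00021
Gilan,0.237,0.185,0.289,0.00071,0.207,0.184,0.23,0.00014,0.266,0.098,0.434,0.00735
Golestan,0.234,0.199,0.269,0.00032,0.202,0.029,0.375,0.0078,0.265,0.217,0.313,0.00059
Hamedan,0.236,0.174,0.298,0.00099,0.206,0.135,0.276,0.0013,0.266,0.196,0.337,0.0013
Hormozgan,0.233,0.079,0.387,0.00616,0.202,0.004,0.401,0.01029,0.264,0.035,0.494,0.01371
Ilam,0.238,-0.158,0.634,0.04082,0.21,-0.082,0.502,0.02221,0.267,-0.132,0.665,0.04133
Isfahan,0.24,0.158,0.322,0.00177,0.214,0.059,0.37,0.00631,0.266,0.117,0.415,0.00577
Kerman,0.236,0.188,0.283,0.00059,0.206,0.189,0.223,8e-05,0.266,0.192,0.339,0.00139
Kermanshah,0.239,0.175,0.304,0.00109,0.212,0.11,0.313,0.0027,0.267,0.221,0.313,0.00055
Khorasan jonoobi,0.233,0.118,0.348,0.00345,0.201,0.19,0.212,3e-05,0.265,0.156,0.374,0.00309
Khorasan razavi,0.238,0.102,0.373,0.00481,0.208,0.119,0.298,0.00209,0.266,0.156,0.377,0.0032
Khorasan shomali,0.233,0.142,0.323,0.00213,0.199,0.068,0.33,0.00447,0.265,0.109,0.422,0.00636
Khozestan,0.237,0.19,0.284,0.00058,0.21,0.197,0.223,5e-05,0.265,0.24,0.289,0.00016
Kohgiloyeh-va-boyer-ahmad,0.236,0.065,0.407,0.00761,0.205,0.119,0.291,0.00192,0.265,0.04,0.491,0.01324
Kurdistan,0.236,0.142,0.33,0.00231,0.207,0.149,0.264,0.00086,0.266,0.195,0.337,0.00132
Lorestan,0.237,-0.023,0.497,0.01762,0.208,-0.038,0.454,0.01579,0.266,0.076,0.455,0.00936
Markazi,0.238,0.165,0.311,0.00139,0.21,0.161,0.259,0.00062,0.267,0.23,0.304,0.00035
Mazandaran,0.235,0.173,0.296,0.00099,0.204,0.191,0.216,4e-05,0.266,0.225,0.307,0.00044
Semnan,0.238,-0.51,0.987,0.14583,0.21,-0.455,0.876,0.11537,0.267,-0.701,1.234,0.2437
Sistan-va-balouchestan,0.233,0.094,0.373,0.00506,0.201,0.181,0.221,0.0001,0.265,-0.08,0.609,0.03092
Tehran,0.243,0.197,0.289,0.00055,0.22,0.194,0.247,0.00018,0.266,0.221,0.312,0.00055
Yazd,0.237,0.135,0.34,0.00274,0.21,0.127,0.293,0.0018,0.266,0.105,0.428,0.00679
Zanjan,0.235,-0.188,0.658,0.04659,0.204,-0.22,0.628,0.04679,0.265,-0.32,0.851,0.08921
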