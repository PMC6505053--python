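area_id,est_total,lo_total,hi_total,mse_total,est_male,lo_male,hi_male,mse_male,est_female,lo_female,hi_female,mse_female
A-gharbi,0.244,0.209,0.279,0.00031,0.196,0.167,0.226,0.00022,0.293,0.172,0.413,0.00376
A-sharghi,0.243,0.211,0.275,0.00027,0.216,0.16,0.272,0.00081,0.271,0.214,0.328,0.00083
Alborz,0.259,0.214,0.303,0.00052,0.251,0.08,0.422,0.00761,0.266,0.214,0.317,0.00069
Ardebil,0.214,0.155,0.272,0.00089,0.193,0.149,0.238,0.00052,0.235,0.151,0.318,0.00183
Booshehr,0.227,0.147,0.307,0.00167,0.22,0.129,0.311,0.00215,0.233,0.147,0.318,0.0019
Chaharmahal-va-bakhtiari,0.196,0.081,0.312,0.00346,0.167,0.06,0.274,0.00297,0.225,0.126,0.325,0.00258
Fars,0.265,0.19,0.34,0.00147,0.235,0.135,0.334,0.00258,0.295,0.17,0.421,0.00411
Ghazvin,0.274,0.174,0.373,0.00258,0.244,0.102,0.387,0.00528,0.305,0.125,0.484,0.00843
Ghom,0.245,0.173,0.316,0.00133,0.228,0.146,0.311,0.00177,0.262,0.202,0.321,0.00092
Gilan,0.241,0.202,0.279,0.00038,0.192,0.156,0.228,0.00033,0.288,0.184,0.391,0.00279
Golestan,0.248,0.21,0.285,0.00036,0.229,0.111,0.347,0.00362,0.266,0.219,0.313,0.00057
Hamedan,0.227,0.179,0.274,0.00059,0.213,0.148,0.278,0.00111,0.241,0.185,0.297,0.00081
Hormozgan,0.267,0.164,0.37,0.00276,0.235,0.099,0.371,0.00481,0.301,0.147,0.454,0.00613
Ilam,0.171,0.087,0.256,0.00184,0.152,-0.043,0.347,0.00987,0.192,-0.079,0.463,0.01911
Isfahan,0.259,0.207,0.312,0.00072,0.236,0.14,0.333,0.00242,0.283,0.19,0.376,0.00225
Kerman,0.223,0.185,0.261,0.00038,0.203,0.17,0.236,0.00028,0.243,0.191,0.295,0.0007
Kermanshah,0.244,0.196,0.291,0.00058,0.223,0.15,0.296,0.00138,0.264,0.215,0.313,0.00063
Khorasan jonoobi,0.238,0.152,0.324,0.00191,0.196,0.147,0.244,0.00061,0.278,0.187,0.368,0.00212
Khorasan razavi,0.208,0.125,0.292,0.0018,0.182,0.124,0.241,0.00089,0.234,0.164,0.304,0.00126
Khorasan shomali,0.223,0.155,0.292,0.00122,0.218,0.116,0.321,0.00271,0.228,0.124,0.332,0.00282
Khozestan,0.224,0.191,0.258,0.00029,0.2,0.177,0.222,0.00013,0.25,0.221,0.278,0.0002
Kohgiloyeh-va-boyer-ahmad,0.2,0.084,0.315,0.00348,0.181,0.106,0.255,0.00143,0.22,0.065,0.375,0.00629
Kurdistan,0.215,0.154,0.276,0.00098,0.188,0.144,0.232,0.00051,0.242,0.187,0.297,0.00079
Lorestan,0.183,0.026,0.339,0.00636,0.148,0.002,0.295,0.00561,0.217,0.099,0.335,0.00362
Markazi,0.236,0.183,0.29,0.00074,0.211,0.16,0.262,0.00067,0.262,0.213,0.311,0.00062
Mazandaran,0.219,0.178,0.26,0.00044,0.192,0.163,0.222,0.00023,0.245,0.211,0.279,0.0003
Semnan,0.364,-0.144,0.871,0.06707,0.314,-0.139,0.767,0.05339,0.415,-0.245,1.075,0.11352
Sistan-va-balouchestan,0.266,0.176,0.356,0.00212,0.201,0.164,0.238,0.00036,0.329,0.115,0.544,0.01196
Tehran,0.231,0.201,0.262,0.00025,0.203,0.178,0.228,0.00016,0.26,0.227,0.293,0.00028
Yazd,0.234,0.161,0.308,0.00141,0.185,0.121,0.248,0.00105,0.288,0.169,0.407,0.0037
Zanjan,0.319,0.043,0.596,0.01995,0.279,0.004,0.554,0.01963,0.36,-0.027,0.748,0.03917
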