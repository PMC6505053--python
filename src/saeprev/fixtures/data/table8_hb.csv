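area_id,est_total,lo_total,hi_total,mse_total,est_male,lo_male,hi_male,mse_male,est_female,lo_female,hi_female,mse_female
A-gharbi,0.245,0.2,0.291,0.00052,0.184,0.135,0.239,0.00071,0.314,0.249,0.383,0.00116
A-sharghi,0.224,0.184,0.264,0.00043,0.201,0.154,0.253,0.00065,0.255,0.201,0.314,0.00083
Alborz,0.277,0.217,0.337,0.00052,0.287,0.204,0.384,0.00213,0.269,0.2,0.347,0.0014
Ardebil,0.178,0.12,0.236,0.00081,0.177,0.112,0.254,0.00132,0.215,0.141,0.3,0.00163
Booshehr,0.234,0.166,0.303,0.00128,0.203,0.129,0.29,0.00168,0.273,0.19,0.369,0.00207
Chaharmahal-va-bakhtiari,0.166,0.107,0.225,0.00096,0.158,0.09,0.237,0.00143,0.215,0.142,0.298,0.0016
Fars,0.281,0.241,0.321,0.00038,0.25,0.2,0.304,0.0007,0.318,0.263,0.377,0.00084
Ghazvin,0.252,0.186,0.318,0.00118,0.233,0.162,0.316,0.00156,0.266,0.184,0.359,0.00198
Ghom,0.262,0.193,0.331,0.00127,0.227,0.152,0.316,0.00174,0.293,0.211,0.386,0.00202
Gilan,0.23,0.182,0.279,0.0006,0.175,0.12,0.237,0.00091,0.294,0.229,0.363,0.00117
Golestan,0.253,0.194,0.312,0.00092,0.237,0.164,0.325,0.00169,0.273,0.203,0.351,0.00142
Hamedan,0.201,0.147,0.254,0.00079,0.201,0.134,0.28,0.00138,0.202,0.138,0.276,0.00125
Hormozgan,0.258,0.197,0.318,0.00097,0.213,0.146,0.292,0.00139,0.299,0.224,0.382,0.00162
Ilam,0.175,0.109,0.241,0.00013,0.152,0.076,0.241,0.00179,0.187,0.092,0.27,0.00021
Isfahan,0.284,0.245,0.323,0.00037,0.27,0.22,0.324,0.00072,0.303,0.252,0.358,0.00074
Kerman,0.211,0.169,0.253,0.00037,0.21,0.152,0.275,0.00098,0.212,0.16,0.27,0.00079
Kermanshah,0.252,0.197,0.306,0.00058,0.246,0.179,0.323,0.00135,0.268,0.199,0.344,0.00137
Khorasan jonoobi,0.26,0.179,0.342,0.00182,0.203,0.124,0.301,0.00201,0.304,0.209,0.415,0.00278
Khorasan razavi,0.159,0.13,0.188,0.00022,0.139,0.101,0.182,0.00044,0.196,0.157,0.237,0.00042
Khorasan shomali,0.205,0.14,0.27,0.00117,0.206,0.128,0.304,0.00199,0.192,0.117,0.278,0.00168
Khozestan,0.195,0.159,0.231,0.00023,0.191,0.146,0.24,0.00058,0.218,0.169,0.272,0.0007
Kohgiloyeh-va-boyer-ahmad,0.184,0.119,0.249,0.0012,0.161,0.092,0.242,0.00149,0.202,0.119,0.298,0.00208
Kurdistan,0.188,0.134,0.243,0.00071,0.179,0.119,0.246,0.00104,0.228,0.154,0.311,0.0016
Lorestan,0.126,0.085,0.166,0.00047,0.119,0.068,0.177,0.0008,0.185,0.124,0.252,0.00108
Markazi,0.205,0.148,0.261,0.00072,0.188,0.121,0.267,0.00141,0.242,0.172,0.318,0.00142
Mazandaran,0.201,0.162,0.24,0.00039,0.183,0.127,0.247,0.00093,0.205,0.157,0.259,0.00069
Semnan,0.365,0.254,0.476,0.00321,0.345,0.223,0.496,0.00499,0.384,0.265,0.524,0.00443
Sistan-va-balouchestan,0.3,0.249,0.351,0.00068,0.197,0.142,0.258,0.00088,0.378,0.308,0.451,0.00134
Tehran,0.194,0.166,0.222,0.00018,0.165,0.131,0.203,0.00034,0.238,0.198,0.28,0.00044
Yazd,0.248,0.178,0.319,0.00135,0.211,0.133,0.307,0.00196,0.289,0.207,0.383,0.00202
Zanjan,0.361,0.28,0.442,0.0017,0.274,0.187,0.383,0.00252,0.388,0.29,0.495,0.00276
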