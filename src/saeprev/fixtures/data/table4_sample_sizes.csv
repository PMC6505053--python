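area_id,n_male,prop_male,n_female,prop_female,n_total,prop_total
A-gharbi,170,5.02,179,3.98,349,4.43
A-sharghi,212,6.26,207,4.6,419,5.31
Alborz,72,2.13,123,2.73,195,2.47
Ardebil,61,1.8,71,1.58,132,1.67
Booshehr,49,1.45,64,1.42,113,1.43
Chaharmahal-va-bakhtiari,45,1.33,69,1.53,114,1.45
Fars,239,7.06,295,6.56,534,6.77
Ghazvin,73,2.16,65,1.44,138,1.75
Ghom,63,1.86,72,1.6,135,1.71
Gilan,109,3.22,167,3.71,276,3.5
Golestan,69,2.04,109,2.42,178,2.26
Hamedan,67,1.98,96,2.13,163,2.07
Hormozgan,76,2.24,100,2.22,176,2.23
Ilam,25,0.74,35,0.78,60,0.76
Isfahan,263,7.76,319,7.09,582,7.38
Kerman,124,3.66,199,4.42,323,4.1
Kermanshah,101,2.98,127,2.82,228,2.89
Khorasan jonoobi,35,1.03,43,0.96,78,0.99
Khorasan razavi,236,6.97,387,8.6,623,7.9
Khorasan shomali,38,1.12,53,1.18,91,1.15
Khozestan,236,6.97,258,5.73,494,6.26
Kohgiloyeh-va-boyer-ahmad,38,1.12,42,0.93,80,1.01
Kurdistan,95,2.8,78,1.73,173,2.19
Lorestan,102,3.01,117,2.6,219,2.78
Markazi,64,1.89,96,2.13,160,2.03
Mazandaran,111,3.28,226,5.02,337,4.27
Semnan,33,0.97,36,0.8,69,0.87
Sistan-va-balouchestan,132,3.9,178,3.96,310,3.93
Tehran,352,10.39,541,12.02,893,11.32
Yazd,47,1.39,74,1.64,121,1.53
Zanjan,50,1.48,73,1.62,123,1.56
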