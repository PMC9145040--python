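analyte,lod_ng_ml,loq_ng_ml,range_low,range_high,intercept,intercept_sd,slope,slope_sd,r2,r2_sd
Mephedrone,0.22,1,1,1000,0.0023,0.0079,0.1173,0.0119,0.9974,0.0009
Methylone,0.11,1,1,1000,-0.0105,0.0037,0.1154,0.0168,0.9978,0.0021
Methedrone,0.37,1,1,1000,0.0013,0.0075,0.0662,0.0039,0.9975,0.0026
Ethylone,0.23,1,1,1000,-0.0005,0.0084,0.1206,0.0094,0.9983,0.0019
Butylone,0.29,1,1,1000,0.0032,0.0028,0.0309,0.0013,0.9979,0.0015
Dibutylone,0.23,1,1,1000,0.0024,0.0120,0.1714,0.0256,0.9977,0.0015
4-CEC,0.09,1,1,1000,-0.0042,0.0017,0.0662,0.0038,0.9984,0.0013
4-Cl-alpha-PPP,0.30,1,1,1000,0.0079,0.0193,0.2147,0.0172,0.9979,0.0014
N-ethylpentylone,0.26,1,1,1000,0.0104,0.0083,0.1045,0.0039,0.9984,0.0007
4-EMC,0.11,1,1,1000,0.0068,0.0035,0.1021,0.0064,0.9984,0.0016
alpha-PVP,0.13,1,1,1000,-0.0219,0.0090,0.2255,0.0157,0.9988,0.0008
MDPV,0.35,1,1,1000,-0.0033,0.0159,0.1511,0.0147,0.9987,0.0009
4-MPD,0.22,1,1,1000,-0.0252,0.0255,0.3841,0.0395,0.9960,0.0039
N-ethylhexedrone,0.25,1,1,1000,-0.0040,0.0141,0.1901,0.0140,0.9993,0.0003
4-F-PHP,0.19,1,1,1000,-0.0246,0.0167,0.2849,0.0234,0.9972,0.0027
4-Cl-alpha-PVP,0.30,1,1,1000,0.0050,0.0162,0.1761,0.0139,0.9990,0.0006
Dihydro-mephedrone,0.39,1,1,1000,0.0174,0.0168,0.1426,0.0212,0.9983,0.0012
Dihydro-MDPV,0.43,1,1,1000,0.0224,0.0104,0.0797,0.0059,0.9985,0.0015
Dihydro-4-Cl-alpha-PPP,0.49,1,1,1000,0.0292,0.0183,0.1223,0.0137,0.9965,0.0030
Dihydro-4-EMC,0.23,1,1,1000,0.0218,0.0114,0.1609,0.0195,0.9984,0.0009
Dihydro-N-ethylhexedrone,0.32,1,1,1000,0.0296,0.0239,0.2455,0.0189,0.9981,0.0014
Dihydro-dibutylone,0.20,1,1,1000,0.0696,0.0700,1.1340,0.1303,0.9989,0.0010
Dihydro-N-ethylpentylone,0.36,1,1,1000,0.0305,0.0176,0.1610,0.0121,0.9989,0.0013
Dihydro-4-MPD,0.25,1,1,1000,0.1267,0.0559,0.7330,0.0820,0.9982,0.0011
Dihydro-4-CEC,0.24,1,1,1000,0.0125,0.0058,0.0802,0.0076,0.9983,0.0013
Dihydro-4-F-PHP,0.30,1,1,1000,-0.0081,0.0436,0.4782,0.0213,0.9988,0.0011
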