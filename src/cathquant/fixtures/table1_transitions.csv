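analyte,role,rt_min,precursor_mz,product_mz,kind,cone_v,ce_ev,dwell_s,ion_ratio
Methylone,parent,5.23,208,160,quantifier,22,17,0.150,0.27
Methylone,parent,5.23,208,132,qualifier,22,25,0.150,0.27
Ethylone,parent,5.63,222,174,quantifier,24,19,0.050,0.18
Ethylone,parent,5.63,222,146,qualifier,24,24,0.050,0.18
Methedrone,parent,5.63,194,161,quantifier,23,19,0.010,0.34
Methedrone,parent,5.63,194,176,qualifier,23,12,0.010,0.34
Dihydro-mephedrone,metabolite,5.64,180,131,quantifier,24,18,0.050,
Dihydro-mephedrone,metabolite,5.64,180,147,qualifier,24,19,0.050,
Mephedrone,parent,5.72,178,145,quantifier,24,20,0.050,0.52
Mephedrone,parent,5.72,178,160,qualifier,24,12,0.050,0.52
Butylone,parent,5.94,222,146,quantifier,24,24,0.020,0.28
Butylone,parent,5.94,222,204,qualifier,24,13,0.020,0.28
Dihydro-dibutylone,metabolite,6.02,238,220,quantifier,26,12,0.050,
Dihydro-dibutylone,metabolite,6.02,238,191,qualifier,26,20,0.050,
Dibutylone,parent,6.07,236,86,quantifier,26,21,0.050,0.60
Dibutylone,parent,6.07,236,191,qualifier,26,15,0.050,0.60
Dihydro-N-ethylpentylone,metabolite,6.49,252,191,quantifier,27,23,0.010,
Dihydro-N-ethylpentylone,metabolite,6.49,252,234,qualifier,27,15,0.010,
N-ethylpentylone,parent,6.60,250,202,quantifier,27,18,0.010,0.76
N-ethylpentylone,parent,6.60,250,232,qualifier,27,13,0.010,0.76
4-CEC,parent,6.63,212,159,quantifier,27,18,0.050,0.74
4-CEC,parent,6.63,212,194,qualifier,27,13,0.050,0.74
Dihydro-4-CEC,metabolite,6.71,214,181,quantifier,23,23,0.050,
Dihydro-4-CEC,metabolite,6.71,214,141,qualifier,23,14,0.050,
Dihydro-4-EMC,metabolite,6.84,194,117,quantifier,26,22,0.010,
Dihydro-4-EMC,metabolite,6.84,194,176,qualifier,26,12,0.010,
4-Cl-alpha-PPP,parent,6.87,238,139,quantifier,30,27,0.010,0.87
4-Cl-alpha-PPP,parent,6.87,238,98,qualifier,30,25,0.010,0.87
4-EMC,parent,6.92,192,145,quantifier,26,21,0.010,0.51
4-EMC,parent,6.92,192,174,qualifier,26,12,0.010,0.51
Dihydro-4-Cl-alpha-PPP,metabolite,6.96,240,207,quantifier,30,22,0.010,
Dihydro-4-Cl-alpha-PPP,metabolite,6.96,240,115,qualifier,30,30,0.010,
alpha-PVP,parent,7.00,232,91,quantifier,35,25,0.010,0.24
alpha-PVP,parent,7.00,232,105,qualifier,35,21,0.010,0.24
MDPV,parent,7.16,276,126,quantifier,30,27,0.010,0.52
MDPV,parent,7.16,276,135,qualifier,30,24,0.010,0.52
Dihydro-4-MPD,metabolite,7.17,208,147,quantifier,25,22,0.010,
Dihydro-4-MPD,metabolite,7.17,208,159,qualifier,25,16,0.010,
Dihydro-MDPV,metabolite,7.19,278,217,quantifier,30,22,0.010,
Dihydro-MDPV,metabolite,7.19,278,260,qualifier,30,16,0.010,
4-MPD,parent,7.25,206,188,quantifier,25,13,0.010,0.45
4-MPD,parent,7.25,206,145,qualifier,25,20,0.010,0.45
N-ethylhexedrone,parent,7.48,220,202,quantifier,27,14,0.010,0.55
N-ethylhexedrone,parent,7.48,220,91,qualifier,27,22,0.010,0.55
Dihydro-N-ethylhexedrone,metabolite,7.55,222,147,quantifier,27,23,0.010,
Dihydro-N-ethylhexedrone,metabolite,7.55,222,117,qualifier,27,22,0.010,
4-F-PHP,parent,7.90,264,109,quantifier,35,25,0.050,0.39
4-F-PHP,parent,7.90,264,140,qualifier,35,30,0.050,0.39
4-Cl-alpha-PVP,parent,7.92,266,125,quantifier,31,21,0.050,0.26
4-Cl-alpha-PVP,parent,7.92,266,139,qualifier,31,24,0.050,0.26
Dihydro-4-F-PHP,metabolite,8.01,266,109,quantifier,35,25,0.050,
Dihydro-4-F-PHP,metabolite,8.01,266,191,qualifier,35,20,0.050,
MDPV-d8,internal_standard,6.84,284,134,quantifier,33,26,0.020,
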