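analyte,nominal_ng_ml,cv_run1,cv_run2,cv_run3,cv_run4,cv_run5,bias_run1,bias_run2,bias_run3,bias_run4,bias_run5,grand_mean,bias_pct,within_run_cv,between_run_cv
Mephedrone,30,5.6,4.4,6.8,2.9,4.7,-2.7,-19.3,-12.5,-17.2,-16.2,25.7,-14.4,7.7,7.8
Mephedrone,400,3.6,8.8,4.9,2.5,6.2,-1.9,8.5,10.9,3.6,12.8,429.5,7.4,6.9,7.0
Mephedrone,800,2.5,0.8,7.2,1.2,4.3,3.1,-3.4,6.5,-4.1,12.5,823.4,2.9,7.4,7.6
Methylone,30,0.1,0.7,2.3,0.9,2.0,-16.6,-19.9,-18.3,-10.4,-12.6,25.4,-15.5,4.7,4.9
Methylone,400,3.4,0.6,1.9,2.2,2.9,-1.4,-1.8,8.0,0.6,10.8,414.4,3.6,5.5,5.7
Methylone,800,4.1,1.0,1.6,2.1,3.5,-1.3,2.9,0.0,4.3,17.3,840.7,5.1,7.0,7.2
Methedrone,30,11.0,8.3,8.7,1.9,4.0,0.1,-13.4,-0.8,-15.5,-12.3,27.3,-9.0,9.6,9.7
Methedrone,400,3.6,3.2,5.0,2.2,7.0,-14.9,1.4,-1.9,-8.8,3.3,386.4,-3.4,7.9,8.1
Methedrone,800,2.0,2.0,2.5,2.4,4.4,-1.0,-2.5,-4.6,-3.0,2.1,787.0,-1.6,3.5,3.5
Ethylone,30,0.9,3.7,5.3,5.7,5.5,0.8,-14.2,-7.8,-19.2,-16.3,26.3,-12.2,8.7,9.0
Ethylone,400,6.6,3.6,3.3,2.7,2.1,-9.7,6.7,7.1,1.9,4.5,411.8,0.3,6.2,6.4
Ethylone,800,4.5,0.4,1.9,0.6,2.7,-1.8,-1.6,-2.1,2.6,2.4,800.1,0.0,2.9,3.0
Butylone,30,9.3,8.4,9.2,4.9,1.7,4.2,-12.5,-13.5,-17.8,0.5,27.4,-8.7,11.0,11.3
Butylone,400,0.2,3.2,4.7,5.8,1.4,-18.6,6.9,-0.7,-6.8,2.9,391.4,-2.2,9.3,9.6
Butylone,800,2.9,4.6,0.7,5.2,2.9,-8.0,0.7,-9.2,-5.1,1.5,770.1,-3.7,5.7,5.8
Dibutylone,30,7.1,2.2,3.8,7.1,2.3,7.8,-5.1,-16.8,-12.5,-13.0,27.3,-9.1,9.9,10.2
Dibutylone,400,1.8,13.9,7.7,4.0,3.1,8.0,12.0,0.9,4.5,16.5,433.6,8.4,8.6,8.6
Dibutylone,800,4.6,11.0,10.1,7.6,2.3,-1.7,-0.5,-0.6,9.1,2.8,816.7,2.1,7.8,7.8
4-CEC,30,8.4,1.6,3.7,2.2,1.0,-14.6,-17.2,-18.6,-12.6,-19.2,25.0,-16.6,4.3,4.4
4-CEC,400,1.8,5.1,1.3,3.3,5.3,-8.6,3.1,8.3,5.3,11.6,419.3,4.8,7.0,7.2
4-CEC,800,2.4,2.9,1.1,5.3,0.6,-0.8,-3.2,-1.7,4.0,3.4,803.5,0.4,4.0,4.0
4-Cl-alpha-PPP,30,5.1,9.2,8.5,3.6,2.1,9.3,-8.8,4.7,-10.7,-18.3,28.3,-5.8,12.2,12.5
4-Cl-alpha-PPP,400,3.4,1.5,1.8,3.5,2.2,-12.3,5.2,10.4,8.1,7.8,420.1,7.5,7.5,7.8
4-Cl-alpha-PPP,800,4.0,1.4,1.0,0.5,2.1,6.2,-5.5,0.5,2.7,7.1,815.4,1.9,4.9,5.1
N-ethylpentylone,30,0.6,6.0,3.1,2.0,8.8,11.6,-12.6,2.7,-12.1,-14.5,28.2,-6.2,11.5,11.8
N-ethylpentylone,400,6.8,5.7,2.2,3.3,3.3,1.5,0.3,11.1,6.3,8.4,423.2,5.8,5.3,5.4
N-ethylpentylone,800,2.2,3.7,1.9,3.8,1.5,-4.0,-6.1,-3.9,-0.3,0.9,779.4,-2.6,3.7,3.7
4-EMC,30,5.8,5.0,2.8,3.3,7.5,-3.5,-7.1,3.9,-19.7,-14.6,27.4,-8.5,10.5,10.8
4-EMC,400,3.5,5.2,2.9,4.7,4.6,-12.3,2.2,3.7,2.6,2.6,402.4,0.6,6.6,6.7
4-EMC,800,2.2,3.1,0.9,5.6,2.0,3.3,1.7,-1.4,1.8,2.5,811.5,1.4,3.2,3.2
alpha-PVP,30,1.2,0.5,5.9,1.6,0.7,-9.7,-19.5,-17.5,-18.2,-16.9,24.9,-16.9,4.5,4.6
alpha-PVP,400,8.3,6.0,3.4,6.2,2.0,-7.5,-2.6,4.9,0.9,3.0,401.0,0.3,6.0,6.1
alpha-PVP,800,1.7,3.8,0.8,2.7,4.9,0.9,-3.6,0.2,4.2,5.8,812.3,1.5,4.4,4.5
MDPV,30,10.7,10.2,4.5,1.8,5.6,5.0,-10.9,-18.1,-15.4,-16.7,26.6,-11.2,7.9,12.5
MDPV,400,0.3,5.3,4.4,4.5,5.7,-0.6,7.0,6.0,0.6,5.9,415.1,3.8,4.5,5.0
MDPV,800,1.7,5.3,1.3,2.6,4.5,-3.6,1.2,3.5,0.9,9.2,817.9,2.2,3.5,5.4
4-MPD,30,3.0,1.9,3.1,5.5,4.3,9.8,5.2,-7.8,-17.9,-18.6,27.9,-7.0,12.9,13.4
4-MPD,400,2.0,6.3,0.4,3.2,1.7,-5.7,-2.8,4.5,1.1,8.7,406.7,1.7,5.8,5.9
4-MPD,800,8.5,0.6,1.4,1.9,2.4,9.3,-0.7,0.1,-2.3,2.7,809.5,1.2,4.9,4.9
N-ethylhexedrone,30,0.6,2.0,2.0,3.3,0.2,-1.4,-5.3,-7.4,-18.8,-17.5,26.8,-10.7,8.0,8.3
N-ethylhexedrone,400,2.8,4.5,1.0,1.6,0.8,-0.9,0.2,2.3,5.6,3.6,409.4,2.4,3.1,3.1
N-ethylhexedrone,800,1.6,0.9,1.9,1.3,4.1,8.3,-3.1,0.7,3.7,7.2,824.1,3.0,4.6,4.7
4-F-PHP,30,4.6,0.9,2.9,0.5,5.0,-8.3,-17.0,-13.8,-16.9,-13.0,25.8,-14.2,4.5,4.6
4-F-PHP,400,1.8,5.0,2.2,3.3,5.0,-10.1,-1.7,2.1,-10.0,3.2,388.8,-2.8,6.9,7.1
4-F-PHP,800,2.4,2.2,3.7,3.5,1.8,-1.4,-3.6,2.8,-9.6,4.8,788.9,-1.4,6.0,6.2
4-Cl-alpha-PVP,30,6.0,8.4,2.3,0.9,1.6,-0.3,-18.2,-17.6,-19.7,-19.9,25.1,-16.2,9.0,9.3
4-Cl-alpha-PVP,400,4.4,2.2,1.2,2.3,0.4,-11.5,0.1,-1.7,-2.3,8.8,397.6,-0.6,6.6,6.8
4-Cl-alpha-PVP,800,0.1,2.0,1.0,0.7,2.0,-1.4,-1.4,-5.9,-4.8,4.8,785.8,-1.8,4.3,4.4
Dihydro-mephedrone,30,0.9,8.8,5.9,5.4,7.8,16.0,-0.1,13.3,-4.2,4.5,31.5,5.1,9.2,9.4
Dihydro-mephedrone,400,6.1,7.3,3.2,0.8,0.4,7.1,13.5,10.3,1.6,3.2,428.6,7.1,5.8,5.9
Dihydro-mephedrone,800,3.1,4.5,2.9,0.9,2.2,7.1,13.5,10.3,1.6,3.2,767.0,-4.1,3.1,3.1
Dihydro-MDPV,30,3.6,8.6,12.3,4.9,8.0,17.2,6.7,-0.6,-5.3,-4.4,30.5,1.7,10.5,10.6
Dihydro-MDPV,400,6.9,4.4,6.7,2.2,1.5,-1.5,8.5,8.5,2.7,1.0,410.7,2.7,5.1,5.1
Dihydro-MDPV,800,0.6,1.7,5.4,1.8,3.3,-6.5,-9.9,-5.2,-8.9,0.4,752.1,-6.0,5.0,5.1
Dihydro-4-Cl-alpha-PPP,30,10.3,7.5,10.5,8.4,3.7,13.0,-5.7,-3.1,-11.2,-10.7,28.1,-6.4,8.5,8.5
Dihydro-4-Cl-alpha-PPP,400,0.5,5.8,5.3,3.6,1.2,-0.4,7.6,10.1,5.7,11.8,429.9,7.5,5.1,5.2
Dihydro-4-Cl-alpha-PPP,800,5.5,5.0,6.7,7.6,8.7,-8.4,-2.7,-10.5,-1.6,2.8,769.9,-3.8,7.8,7.9
Dihydro-4-EMC,30,3.2,9.3,4.0,7.9,9.3,18.0,3.8,12.2,-6.0,2.4,31.6,5.2,9.9,10.1
Dihydro-4-EMC,400,3.1,1.7,2.1,3.8,1.7,-6.0,7.8,14.1,10.8,15.7,438.1,9.5,6.9,7.1
Dihydro-4-EMC,800,6.9,0.3,2.0,2.6,0.7,-3.3,-3.9,-2.0,1.6,4.6,796.8,-0.4,4.1,4.2
Dihydro-N-ethylhexedrone,30,2.0,3.6,2.6,0.6,3.8,5.0,1.4,-2.3,-1.3,-8.6,29.5,-1.6,5.1,5.3
Dihydro-N-ethylhexedrone,400,1.4,3.7,1.4,1.2,2.1,-1.8,7.8,10.6,11.5,12.3,435.2,8.8,4.7,4.9
Dihydro-N-ethylhexedrone,800,3.5,1.9,2.6,4.1,4.0,-1.4,-7.0,2.9,3.0,3.1,801.9,0.2,5.1,5.2
Dihydro-dibutylone,30,3.3,3.9,7.7,8.9,4.6,-2.1,-6.2,9.1,-5.3,-4.9,29.4,-1.9,8.2,8.3
Dihydro-dibutylone,400,3.6,2.2,1.0,2.0,1.6,-8.5,12.7,13.7,11.0,0.3,427.4,6.8,7.9,8.2
Dihydro-dibutylone,800,1.0,1.2,0.2,1.0,1.7,1.3,-4.1,-1.7,2.7,2.3,800.1,0.0,2.9,3.0
Dihydro-N-ethylpentylone,30,8.7,7.8,2.5,7.9,2.2,7.4,-9.3,2.0,-2.1,-8.9,29.1,-2.9,8.3,8.4
Dihydro-N-ethylpentylone,400,4.6,0.4,3.2,7.0,2.9,-4.9,5.3,7.7,12.8,13.0,430.5,7.6,6.7,6.9
Dihydro-N-ethylpentylone,800,0.3,1.5,4.6,2.6,2.3,-11.9,-0.8,-4.2,7.5,2.1,794.3,-0.7,6.7,7.0
Dihydro-4-MPD,30,2.8,4.5,6.0,5.0,2.7,18.3,3.0,3.6,-1.4,6.6,31.5,5.2,7.0,7.1
Dihydro-4-MPD,400,1.4,8.1,1.6,7.2,9.6,-9.4,-1.7,3.5,5.3,15.7,414.2,3.5,9.9,10.1
Dihydro-4-MPD,800,0.1,1.4,3.6,3.9,5.7,-1.4,-8.3,2.8,0.7,6.4,801.1,0.1,6.1,6.3
Dihydro-4-CEC,30,6.8,6.8,9.4,3.0,5.2,15.3,0.3,7.6,-3.0,0.0,31.0,3.2,8.3,8.4
Dihydro-4-CEC,400,1.7,2.1,3.5,1.7,4.0,6.0,12.9,13.0,12.7,-4.4,432.8,8.2,7.1,7.3
Dihydro-4-CEC,800,0.0,1.3,1.3,2.0,1.5,1.8,-2.3,-2.2,1.4,-0.7,795.6,-0.5,2.2,2.2
Dihydro-4-F-PHP,30,10.2,6.9,1.2,0.2,1.0,-3.0,-17.8,-15.7,-12.0,-17.2,25.8,7.2,7.2,7.4
Dihydro-4-F-PHP,400,11.6,2.4,15.0,8.3,0.9,-11.6,4.1,-1.9,6.4,10.9,410.1,2.5,10.2,10.4
Dihydro-4-F-PHP,800,0.4,5.7,4.8,4.0,4.7,0.0,-5.1,0.5,0.5,4.8,801.1,0.1,5.1,5.1
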