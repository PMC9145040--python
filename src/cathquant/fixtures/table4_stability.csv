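analyte,loss_24h_low,rsd_24h_low,loss_24h_high,rsd_24h_high,loss_48h_low,rsd_48h_low,loss_48h_high,rsd_48h_high,loss_72h_low,rsd_72h_low,loss_72h_high,rsd_72h_high
Mephedrone,-1.1,1.0,1.0,3.6,-2.9,1.8,0.4,2.3,-2.0,2.7,-1.1,1.0
Methylone,9.2,5.2,0.0,3.4,-8.3,7.0,-5.1,2.4,-8.1,12.6,9.2,5.2
Methedrone,-6.2,18.3,-11.6,2.2,-8.5,15.6,-11.9,4.9,-12.3,14.6,-6.2,18.3
Ethylone,-7.1,6.2,1.7,2.4,-12.2,6.6,-1.7,4.0,-14.5,6.8,-0.4,4.5
Butylone,3.8,2.6,-5.9,8.8,-14.2,17.0,-13.0,5.4,-12.7,8.9,-11.7,3.1
Dibutylone,5.7,3.5,0.2,2.9,4.1,6.5,-0.3,1.8,-6.5,5.2,-1.3,1.1
4-CEC,0.3,8.1,-8.5,8.8,5.1,14.3,-2.5,9.8,2.0,4.3,-3.5,4.4
4-Cl-alpha-PPP,-2.2,6.6,-5.5,3.1,3.2,8.4,-2.2,1.2,1.4,8.9,-4.8,2.2
N-ethylpentylone,0.1,9.6,-9.2,8.5,-8.5,10.6,-4.3,2.0,-2.1,7.2,-11.4,0.6
4-EMC,-9.4,14.4,-6.8,9.8,-6.6,14.9,2.1,2.0,-7.0,6.3,-1.2,7.8
alpha-PVP,-3.2,4.8,-10.8,3.3,9.9,14.3,-5.6,1.5,0.4,3.1,-13.3,2.1
MDPV,3.6,8.0,-8.8,17.3,5.6,8.9,0.3,3.7,1.7,8.0,-1.2,7.4
4-MPD,1.5,6.9,-0.7,5.3,-3.0,13.9,-1.0,2.8,-0.5,5.5,-10.5,6.6
N-ethylhexedrone,-3.6,13.1,-6.5,2.7,-5.9,12.2,1.8,1.0,-5.8,6.1,-5.7,2.1
4-F-PHP,-7.7,12.8,-9.0,4.8,-6.5,3.4,-2.4,0.3,-13.8,3.9,-11.0,0.6
4-Cl-alpha-PVP,-10.1,17.4,-7.0,14.4,-12.6,12.0,-4.8,2.9,-16.1,7.4,-11.8,3.0
Dihydro-mephedrone,-12.5,11.5,-5.4,5.0,-17.3,15.0,-4.2,5.0,-15.1,12.5,-2.4,1.9
Dihydro-MDPV,-13.0,15.0,-10.3,8.3,-7.7,11.9,1.3,5.3,-18.0,6.3,-5.4,8.5
Dihydro-4-Cl-alpha-PPP,8.8,15.6,-3.4,2.3,10.8,10.3,-4.0,4.3,6.8,14.8,-6.6,3.1
Dihydro-4-EMC,-1.9,3.3,-5.7,2.7,-0.7,17.6,3.2,1.7,-17.0,6.3,-3.9,2.3
Dihydro-N-ethylhexedrone,-3.9,11.1,-3.8,6.1,2.0,16.5,6.6,3.0,-1.6,3.3,-2.1,0.9
Dihydro-dibutylone,-3.8,11.8,-7.9,6.8,4.8,13.9,-6.5,2.0,-8.6,21.0,-8.0,1.8
Dihydro-N-ethylpentylone,-3.0,2.1,-9.1,3.9,-5.4,6.2,-5.6,3.0,-1.7,5.9,-9.4,2.5
Dihydro-4-MPD,3.9,13.8,-5.3,10.9,0.7,15.1,-2.2,2.9,1.6,8.5,-7.9,1.1
Dihydro-4-CEC,-3.2,11.1,-4.7,5.3,5.5,4.0,-1.8,2.8,-3.0,6.1,-4.1,2.0
Dihydro-4-F-PHP,-8.8,6.3,-12.7,13.0,-3.3,11.8,-9.2,7.7,-5.4,12.5,-10.9,1.9
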