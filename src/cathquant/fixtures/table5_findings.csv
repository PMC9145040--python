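sample_no,finding_type,analyte,reported
19,target,Dihydro-mephedrone,172
19,screen,Methamphetamine,+
34,target,N-ethylpentylone,52
34,target,Dihydro-N-ethylpentylone,1378
34,screen,Methamphetamine,+++
49,target,Mephedrone,1537
49,target,Dihydro-mephedrone,>5000
49,screen,Methamphetamine,+++
49,screen,MDMA,+
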