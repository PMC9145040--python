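analyte,role,rt_min,precursor_mz,product_mz,kind,cone_v,ce_ev,dwell_s,ion_ratio
Methamphetamine,qualitative_screen,3.10,150,119,quantifier,25,15,0.020,
Methamphetamine,qualitative_screen,3.10,150,91,qualifier,25,20,0.020,
MDMA,qualitative_screen,3.60,194,163,quantifier,25,15,0.020,
MDMA,qualitative_screen,3.60,194,105,qualifier,25,25,0.020,
MDPV-d8,internal_standard,6.84,284,134,quantifier,33,26,0.020,
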