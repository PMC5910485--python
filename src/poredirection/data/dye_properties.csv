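name,charge,mw_da,cross_section_nm,D_calc_m2_s
YP1,2,375,1.1,4.2e-10
Pr,2,414,1.4,3.2e-10
calcein,-4,622,1.2,
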