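patient,course,ctv_high_v100,ctv_high_dmax,ctv_mid_v100,ctv_low_v100,right_parotid_dmean,left_parotid_dmean,oral_cavity_dmean,brainstem_d003,spinal_cord_d003,total
5,nominal,6.0,5.2,–,6.2,−6.1,6.1,7.0,7.0,7.0,38.4
5,offline,4.2,5.0,–,5.0,−7.7,5.2,7.0,7.0,7.0,32.7
5,online,4.3,6.4,–,6.3,−8.5,3.8,7.0,7.0,7.0,33.3
5,online-f,5.5,6.0,–,6.5,−3.3,5.3,7.0,7.0,7.0,41.0
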