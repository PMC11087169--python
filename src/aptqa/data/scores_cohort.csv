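patient,course,ctv_high_v100,ctv_high_dmax,ctv_mid_v100,ctv_low_v100,right_parotid_dmean,left_parotid_dmean,oral_cavity_dmean,brainstem_d003,spinal_cord_d003,total
1,nominal,−7.7,5.2,2.2,6.1,7.0,7.0,7.0,7.0,7.0,40.8
1,offline,−19.5,3.7,−0.3,4.8,7.0,7.0,7.0,7.0,7.0,23.7
1,online,−18.0,6.3,2.2,6.2,7.0,7.0,7.0,7.0,7.0,31.7
2,nominal,5.2,5.2,6.2,6.1,7.0,6.4,7.0,7.0,7.0,57.1
2,offline,0.3,5.3,5.6,−9.2,7.0,6.5,7.0,7.0,7.0,36.5
2,online,5.9,6.1,6.8,6.0,7.0,7.0,7.0,7.0,7.0,59.8
3,nominal,6.9,4.3,5.5,6.1,1.8,7.0,2.4,7.0,7.0,48.0
3,offline,5.2,1.3,−2.0,6.1,0.6,7.0,−3.6,7.0,7.0,28.6
3,online,5.8,6.0,4.3,6.0,7.0,7.0,5.4,7.0,7.0,55.5
4,nominal,5.2,5.2,5.8,5.4,7.0,7.0,7.0,7.0,7.0,56.6
4,offline,3.7,5.4,5.8,2.3,7.0,7.0,7.0,7.0,7.0,52.2
4,online,4.8,5.9,5.9,4.3,7.0,7.0,7.0,7.0,7.0,55.9
5,nominal,6.0,5.2,–,6.2,−6.1,6.1,7.0,7.0,7.0,38.4
5,offline,4.2,5.0,–,5.0,−7.7,5.2,7.0,7.0,7.0,32.7
5,online,4.3,6.4,–,6.3,−8.5,3.8,7.0,7.0,7.0,33.3
6,nominal,5.4,5.3,5.7,6.5,5.6,−14.8,−10.0,7.0,7.0,17.7
6,offline,−9.7,4.8,−8.0,5.4,2.5,−13.5,−7.8,7.0,7.0,−12.3
6,online,2.7,6.3,2.5,−5.5,4.8,−11.6,−8.3,7.0,7.0,4.9
7,nominal,6.0,3.2,6.7,6.0,7.0,−2.5,7.0,7.0,7.0,47.4
7,offline,3.7,5.0,6.6,5.3,7.0,−2.5,7.0,7.0,7.0,46.1
7,online,5.6,6.0,6.5,5.5,7.0,−5.1,7.0,7.0,7.0,46.5
8,nominal,−11.0,5.4,–,–,7.0,7.0,−18.4,7.0,7.0,4.0
8,offline,−18.5,5.4,–,–,7.0,7.0,−16.6,7.0,7.0,−1.7
8,online,−10.8,6.6,–,–,7.0,7.0,−16.6,7.0,7.0,7.2
9,nominal,5.3,5.2,–,5.2,5.5,5.6,7.0,7.0,7.0,47.8
9,offline,−17.8,5.5,–,0.2,5.1,2.8,7.0,7.0,7.0,16.8
9,online,2.0,5.6,–,1.5,4.9,4.1,7.0,7.0,7.0,39.1
10,nominal,6.7,5.4,–,6.6,6.7,5.9,6.9,7.0,7.0,52.2
10,offline,4.8,5.4,–,−4.2,5.5,5.0,4.9,7.0,7.0,35.4
10,online,5.5,5.8,–,−2.2,5.8,5.8,6.0,7.0,7.0,40.7
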