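patient,course,structure,V100,D98,Dmax,Dmean,D0.03cc
5,nominal,CTV-High,99.0,100.6,106.4,–,–
5,nominal,CTV-Mid,–,–,–,–,–
5,nominal,CTV-Low,99.2,101.6,–,–,–
5,nominal,Right Parotid,–,–,–,34.9,–
5,nominal,Left Parotid,–,–,–,24.9,–
5,nominal,Oral Cavity,–,–,–,20.9,–
5,nominal,Brainstem,–,–,–,–,3.2
5,nominal,Spinal Cord,–,–,–,–,7.0
5,offline,CTV-High,97.5,99.7,106.9,–,–
5,offline,CTV-Mid,–,–,–,–,–
5,offline,CTV-Low,98.0,99.9,–,–,–
5,offline,Right Parotid,–,–,–,36.2,–
5,offline,Left Parotid,–,–,–,25.8,–
5,offline,Oral Cavity,–,–,–,22.1,–
5,offline,Brainstem,–,–,–,–,4.3
5,offline,Spinal Cord,–,–,–,–,6.9
5,online,CTV-High,97.6,99.8,103.6,–,–
5,online,CTV-Mid,–,–,–,–,–
5,online,CTV-Low,99.3,102.2,–,–,–
5,online,Right Parotid,–,–,–,36.8,–
5,online,Left Parotid,–,–,–,27.0,–
5,online,Oral Cavity,–,–,–,22.2,–
5,online,Brainstem,–,–,–,–,6.6
5,online,Spinal Cord,–,–,–,–,7.7
5,online-f,CTV-High,98.5,100.5,104.6,–,–
5,online-f,CTV-Mid,–,–,–,–,–
5,online-f,CTV-Low,99.5,102.9,–,–,–
5,online-f,Right Parotid,–,–,–,32.6,–
5,online-f,Left Parotid,–,–,–,25.7,–
5,online-f,Oral Cavity,–,–,–,22.2,–
5,online-f,Brainstem,–,–,–,–,6.3
5,online-f,Spinal Cord,–,–,–,–,7.8
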