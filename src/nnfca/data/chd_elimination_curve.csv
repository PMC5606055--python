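stage,removed_feature,accuracy
1,H_C,77.743
2,H_B,78.518
3,cirrhosis,80.644
4,TD,80.920
5,hemoglobin,81.120
6,sex,81.141
7,CRF,81.163
8,smoking,81.018
9,HDL,80.921
10,triglyceride,80.222
11,diabetes,79.522
12,BMI,79.209
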