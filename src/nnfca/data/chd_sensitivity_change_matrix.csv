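feature,age,BMI,To_chole,HDL,SBP,DBP,triglyceride,smoking,diabetes
age,0.080,0.009,0.016,0.004,0.011,0.008,0.009,0.022,0.019
BMI,0.031,0.038,0.019,0.013,0.025,0.026,0.037,0.010,0.036
To_chole,0.021,0.012,0.094,0.017,0.042,0.070,0.013,0.013,0.064
HDL,0.011,0.010,0.011,0.011,0.010,0.008,0.009,0.009,0.002
SBP,0.012,0.007,0.001,0.020,0.041,0.035,0.008,0.013,0.016
DBP,0.496,0.013,0.043,0.017,0.017,0.021,0.001,0.029,0.045
triglyceride,0.009,0.005,0.008,0.008,0.003,0.005,0.009,0.005,0.006
smoking,0.005,0.004,0.004,0.003,0.003,0.008,0.002,0.012,0.007
diabetes,0.002,0.006,0.003,0.007,0.008,0.019,0.005,0.009,0.019
Average,0.074,0.012,0.022,0.011,0.017,0.022,0.010,0.014,0.024
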