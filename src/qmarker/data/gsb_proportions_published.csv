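batch,swertiamarin,gentiopicroside,sweroside
S1,0.037,0.041,0.034
S2,0.024,0.039,0.041
S3,0.017,0.036,0.034
S4,0.042,0.035,0.035
S5,0.039,0.035,0.020
S6,0.031,0.040,0.035
S7,0.015,0.018,0.015
S8,0.014,0.017,0.016
S9,0.032,0.041,0.041
S10,0.040,0.046,0.041
S11,0.040,0.041,0.032
S12,0.038,0.035,0.041
S13,0.036,0.035,0.038
S14,0.035,0.036,0.033
S15,0.034,0.034,0.017
S16,0.030,0.032,0.018
S17,0.027,0.030,0.009
S18,0.027,0.030,0.013
S19,0.026,0.037,0.041
S20,0.015,0.018,0.018
S21,0.016,0.017,0.019
S22,0.030,0.029,0.023
S23,0.046,0.034,0.040
S24,0.029,0.034,0.039
S25,0.020,0.021,0.021
S26,0.020,0.021,0.021
S27,0.019,0.020,0.018
S28,0.020,0.020,0.003
S29,0.020,0.019,0.032
S30,0.010,0.009,0.011
S31,0.016,0.005,0.012
S32,0.011,0.001,0.019
S33,0.005,0.000,0.000
S34,0.027,0.033,0.031
S35,0.018,0.021,0.033
S36,0.012,0.003,0.005
S37,0.009,0.002,0.023
S38,0.017,0.020,0.014
S39,0.014,0.005,0.011
S40,0.010,0.004,0.002
S41,0.012,0.003,0.012
S42,0.000,0.000,0.019
S43,0.010,0.005,0.014
S44,0.014,0.001,0.006
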