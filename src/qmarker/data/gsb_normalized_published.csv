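batch,swertiamarin,gentiopicroside,sweroside
S1,0.804,0.908,0.847
S2,0.517,0.848,0.999
S3,0.377,0.798,0.835
S4,0.911,0.767,0.867
S5,0.864,0.760,0.500
S6,0.670,0.870,0.862
S7,0.324,0.395,0.380
S8,0.305,0.362,0.403
S9,0.703,0.893,1.000
S10,0.880,1.000,0.999
S11,0.873,0.907,0.782
S12,0.832,0.767,1.000
S13,0.790,0.763,0.945
S14,0.771,0.782,0.803
S15,0.739,0.743,0.409
S16,0.649,0.703,0.445
S17,0.585,0.664,0.227
S18,0.587,0.656,0.315
S19,0.580,0.805,0.999
S20,0.321,0.402,0.435
S21,0.359,0.377,0.469
S22,0.647,0.630,0.554
S23,1.000,0.746,0.987
S24,0.633,0.740,0.969
S25,0.435,0.462,0.519
S26,0.430,0.455,0.525
S27,0.410,0.443,0.438
S28,0.440,0.429,0.068
S29,0.430,0.415,0.793
S30,0.221,0.191,0.276
S31,0.348,0.112,0.299
S32,0.242,0.015,0.465
S33,0.109,0.010,0.000
S34,0.584,0.718,0.774
S35,0.405,0.457,0.818
S36,0.264,0.066,0.128
S37,0.187,0.036,0.559
S38,0.375,0.429,0.346
S39,0.303,0.113,0.276
S40,0.228,0.083,0.046
S41,0.263,0.074,0.287
S42,0.000,0.000,0.466
S43,0.230,0.101,0.337
S44,0.297,0.031,0.148
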