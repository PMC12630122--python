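batch,swertiamarin,gentiopicroside,sweroside,total
S1,6.9970,73.4831,0.7078,81.1879
S2,5.0636,70.5988,0.8001,76.4625
S3,4.1179,68.1956,0.7008,73.0142
S4,7.7202,66.7382,0.7201,75.1785
S5,7.4021,66.3978,0.4966,74.2965
S6,6.0958,71.6672,0.7170,78.4800
S7,3.7586,48.9386,0.4239,53.1211
S8,3.6280,47.3974,0.4379,51.4633
S9,6.3182,72.7698,0.8009,79.8889
S10,7.5101,77.8618,0.8002,86.1722
S11,7.4645,73.4008,0.6682,81.5334
S12,7.1861,66.7112,0.8007,74.6980
S13,6.9046,66.5628,0.7676,74.2350
S14,6.7745,67.4656,0.6808,74.9209
S15,6.5587,65.5728,0.4414,72.5729
S16,5.9527,63.6874,0.4635,70.1036
S17,5.5189,61.8256,0.3310,67.6754
S18,5.5354,61.4338,0.3843,67.3535
S19,5.4875,68.5241,0.8000,74.8116
S20,3.7362,49.2868,0.4576,53.4806
S21,3.9933,48.1048,0.4777,52.5759
S22,5.9406,60.2024,0.5297,66.6728
S23,8.3188,65.7163,0.7930,74.8281
S24,5.8430,65.4221,0.7822,72.0473
S25,4.5059,52.1401,0.5083,57.1543
S26,4.4724,51.8324,0.5117,56.8166
S27,4.3371,51.2370,0.4588,56.0330
S28,4.5415,50.5976,0.2339,55.3731
S29,4.4737,49.9166,0.6753,55.0656
S30,3.0641,39.2108,0.3607,42.6356
S31,3.9220,35.4282,0.3748,39.7250
S32,3.2070,30.8135,0.4758,34.4962
S33,2.3056,30.5546,0.1927,33.0530
S34,5.5123,64.3674,0.6635,70.5432
S35,4.3085,51.9048,0.6902,56.9035
S36,3.3528,33.2218,0.2708,36.8454
S37,2.8378,31.8036,0.5329,35.1743
S38,4.1026,50.5867,0.4031,55.0925
S39,3.6178,35.4944,0.3604,39.4726
S40,3.1138,34.0688,0.2205,37.4031
S41,3.3494,33.6087,0.3673,37.3255
S42,1.5733,30.0889,0.4764,32.1386
S43,3.1228,34.9204,0.3976,38.4408
S44,3.5734,31.5828,0.2827,35.4389
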