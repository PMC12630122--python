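batch,pc_score,composite_score,rank
S1,2.03,1.72,6
S2,1.51,1.28,13
S3,0.79,0.67,16
S4,2.05,1.73,5
S5,1.26,1.07,14
S6,1.67,1.41,9
S7,-0.93,-0.79,30
S8,-1,-0.85,31
S9,2.04,1.72,7
S10,2.66,2.25,1
S11,2.07,1.75,4
S12,2.1,1.77,3
S13,1.89,1.6,8
S14,1.63,1.38,10
S15,0.77,0.65,17
S16,0.55,0.46,19
S17,-0.07,-0.06,23
S18,0.08,0.06,22
S19,1.57,1.33,11
S20,-0.83,-0.7,29
S21,-0.73,-0.61,27
S22,0.6,0.51,18
S23,2.43,2.06,2
S24,1.52,1.29,12
S25,-0.29,-0.25,24
S26,-0.31,-0.26,25
S27,-0.53,-0.45,26
S28,-1.15,-0.98,32
S29,0.1,0.08,21
S30,-1.75,-1.48,37
S31,-1.57,-1.32,33
S32,-1.7,-1.44,35
S33,-2.87,-2.42,44
S34,1.01,0.86,15
S35,0.17,0.14,20
S36,-2.16,-1.83,41
S37,-1.62,-1.37,34
S38,-0.81,-0.68,28
S39,-1.71,-1.45,36
S40,-2.36,-2,43
S41,-1.86,-1.57,39
S42,-2.3,-1.95,42
S43,-1.8,-1.52,38
S44,-2.11,-1.79,40
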