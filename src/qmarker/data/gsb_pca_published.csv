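component,eigenvalue,variance_pct,cumulative_pct
1,2.538,84.599,84.599
2,0.357,11.903,96.502
3,0.105,3.498,100.000
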