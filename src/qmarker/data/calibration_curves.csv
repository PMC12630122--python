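analyte,slope,intercept
swertiamarin,4650.7,1.0924
gentiopicroside,5908.2,61.304
sweroside,8083.9,-1.5587
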