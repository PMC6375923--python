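response,b0,b1,b2,b11,b22,b12
TF,1737.8,-106.1,43.8,-86.9,-6.8,47.3
CA,340.7,-22.0,14.6,-23.2,-2.4,1.8
FL,14.0,0.35,0.33,-0.63,-0.27,-0.16
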