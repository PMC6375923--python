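effect,TF,CA,FL
A,-92.88,-19.99,1.12
B,38.54,9.66,-0.05
C,76.98,24.70,0.94
D,149.19,31.99,1.55
E,39.50,18.37,0.40
F,12.65,0.58,0.85
G,-73.20,-13.01,-0.03
A*B,-22.59,-6.84,-0.08
A*C,-14.37,1.38,-0.20
A*D,50.12,4.40,-0.44
A*E,-8.85,-3.20,-0.31
A*F,-24.34,-5.63,-0.08
A*G,-47.06,-3.64,-0.02
B*D,-27.05,1.27,-0.45
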