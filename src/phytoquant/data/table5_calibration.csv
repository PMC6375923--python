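analyte,conc_low_ug_ml,conc_high_ug_ml,slope,intercept,r2_floor,ci_intercept_low,ci_intercept_high,lod_ng_ml,loq_ng_ml
CA,0.16,50.30,67.6,-15.2,0.99,-32.62,2.27,160.7,401.9
VX-1,0.16,211.70,74.4,-12.4,0.99,-42.64,17.92,131.2,328.0
VX-2,1.63,352.83,5.2,-3.4,0.99,-7.16,0.46,423.6,903.8
RU,1.49,194.64,41.4,-11.4,0.99,-23.31,0.57,131.0,388.6
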