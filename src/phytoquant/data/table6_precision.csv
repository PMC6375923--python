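analyte,day1,day2,day3,day4,level_50,level_150,rsd_overall_repeatability,rsd_intermediate_precision,horwitz_rsd_r,horwitz_rsd_R
CA,0.91,1.30,1.43,0.83,0.96,1.14,1.10,4.34,3.79,5.68
TF-1,0.70,0.36,0.58,0.68,0.88,0.70,0.67,3.54,2.92,4.37
TF-2,0.24,0.25,0.32,0.26,0.25,0.23,0.26,2.92,2.58,3.86
FL,1.19,1.39,1.86,0.99,0.91,1.46,1.32,4.77,4.23,6.34
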