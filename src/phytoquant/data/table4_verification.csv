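response,x1_natural,x2_natural,predicted_mean,predicted_sd,experimental_mean,experimental_sd,n_experimental
TF,70,64,1786.0,29.3,1736.3,7.9,3
CA,70,64,356.6,3.6,354.4,3.2,3
FL,70,64,13.9,0.3,14.1,0.3,3
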