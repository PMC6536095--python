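variable,role,mean,sd
hypertension_thousands,need,1.2,1.6
diabetics_thousands,need,337.84,506.9
asthmatics_thousands,need,238.44,333.2
elderly_thousands,need,978.0,71.4
negative_income_index,need,0.5351,0.7119
bppp_value_millions,service,67.6,100.2
bcpa_value_millions,service,38.0,44.33
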