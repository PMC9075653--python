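sex,age_band,annual_probability
male,18-29,0.001125
male,30-39,0.002306
male,40-49,0.004728
male,50-59,0.009692
male,60-69,0.019869
male,70-79,0.040731
male,80+,0.083498
female,18-29,0.0009
female,30-39,0.001845
female,40-49,0.003782
female,50-59,0.007754
female,60-69,0.015895
female,70-79,0.032585
female,80+,0.066798
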