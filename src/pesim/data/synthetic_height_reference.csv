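sex,age_years,median_cm,sd_cm
male,6,116.0,5.5
male,7,122.0,5.5
male,8,127.5,5.5
male,9,132.5,5.5
male,10,137.5,5.5
male,11,142.5,5.5
male,12,148.0,5.5
male,13,155.0,5.5
male,14,162.0,5.5
male,15,167.5,5.5
male,16,171.0,5.5
male,17,172.8,5.5
male,18,173.5,5.5
male,19,174.0,5.5
female,6,115.0,5.5
female,7,121.0,5.5
female,8,126.5,5.5
female,9,132.0,5.5
female,10,138.0,5.5
female,11,144.5,5.5
female,12,151.0,5.5
female,13,155.5,5.5
female,14,158.5,5.5
female,15,160.0,5.5
female,16,161.0,5.5
female,17,161.5,5.5
female,18,162.0,5.5
female,19,162.2,5.5
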