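condition,us_cost_first_year,us_cost_subsequent,disability_weight,avg_duration_years,first_year_ratio_rule
type2_diabetes,9600,9600,0.049,20.0,0
chd,25000,3700,0.08,15.0,0
stroke,21000,3200,0.316,10.0,0
esrd,90000,88000,0.571,5.0,1
breast_cancer,62000,12000,0.288,9.0,1
cervical_cancer,48000,10000,0.288,8.0,1
uterine_cancer,52000,10000,0.288,8.0,1
prostate_cancer,42000,9000,0.288,10.0,1
colorectal_cancer,66000,13000,0.288,7.0,1
esophageal_cancer,74000,15000,0.288,3.0,1
kidney_cancer,60000,12000,0.288,6.0,1
pancreatic_cancer,79000,16000,0.288,2.0,1
stomach_cancer,70000,14000,0.288,4.0,1
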