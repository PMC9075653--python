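condition,case_fatality_first_year,annual_excess_mortality
type2_diabetes,0.01,0.004
chd,0.2,0.015
stroke,0.15,0.018
breast_cancer,0.15,0.03
cervical_cancer,0.25,0.03
uterine_cancer,0.18,0.03
prostate_cancer,0.12,0.03
colorectal_cancer,0.3,0.03
esophageal_cancer,0.6,0.03
kidney_cancer,0.3,0.03
pancreatic_cancer,0.75,0.03
stomach_cancer,0.55,0.03
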