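sex,age_band,from_bmi,to_normal,to_overweight,to_obese
male,18-29,normal,0.98,0.02,0.0
male,18-29,overweight,0.006,0.984,0.01
male,18-29,obese,0.0,0.006,0.994
male,30-39,normal,0.972,0.028,0.0
male,30-39,overweight,0.006,0.98,0.014
male,30-39,obese,0.0,0.006,0.994
male,40-49,normal,0.964,0.036,0.0
male,40-49,overweight,0.006,0.976,0.018
male,40-49,obese,0.0,0.006,0.994
male,50-59,normal,0.956,0.044,0.0
male,50-59,overweight,0.006,0.972,0.022
male,50-59,obese,0.0,0.006,0.994
male,60-69,normal,0.956,0.044,0.0
male,60-69,overweight,0.006,0.972,0.022
male,60-69,obese,0.0,0.006,0.994
male,70-79,normal,0.956,0.044,0.0
male,70-79,overweight,0.006,0.972,0.022
male,70-79,obese,0.0,0.006,0.994
male,80+,normal,0.956,0.044,0.0
male,80+,overweight,0.006,0.972,0.022
male,80+,obese,0.0,0.006,0.994
female,18-29,normal,0.98,0.02,0.0
female,18-29,overweight,0.006,0.984,0.01
female,18-29,obese,0.0,0.006,0.994
female,30-39,normal,0.972,0.028,0.0
female,30-39,overweight,0.006,0.98,0.014
female,30-39,obese,0.0,0.006,0.994
female,40-49,normal,0.964,0.036,0.0
female,40-49,overweight,0.006,0.976,0.018
female,40-49,obese,0.0,0.006,0.994
female,50-59,normal,0.956,0.044,0.0
female,50-59,overweight,0.006,0.972,0.022
female,50-59,obese,0.0,0.006,0.994
female,60-69,normal,0.956,0.044,0.0
female,60-69,overweight,0.006,0.972,0.022
female,60-69,obese,0.0,0.006,0.994
female,70-79,normal,0.956,0.044,0.0
female,70-79,overweight,0.006,0.972,0.022
female,70-79,obese,0.0,0.006,0.994
female,80+,normal,0.956,0.044,0.0
female,80+,overweight,0.006,0.972,0.022
female,80+,obese,0.0,0.006,0.994
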