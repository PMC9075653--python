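sex,age_years,L,M,S
male,6.0,-1.6,15.3,0.085
male,6.5,-1.6,15.375,0.0867
male,7.0,-1.6,15.45,0.0885
male,7.5,-1.6,15.525,0.0902
male,8.0,-1.6,15.6,0.0919
male,8.5,-1.6,15.8,0.0937
male,9.0,-1.6,16.0,0.0954
male,9.5,-1.6,16.2,0.0971
male,10.0,-1.6,16.4,0.0988
male,10.5,-1.6,16.725,0.1006
male,11.0,-1.6,17.05,0.1023
male,11.5,-1.6,17.375,0.104
male,12.0,-1.6,17.7,0.1058
male,12.5,-1.6,18.125,0.1075
male,13.0,-1.6,18.55,0.1092
male,13.5,-1.6,18.975,0.111
male,14.0,-1.6,19.4,0.1127
male,14.5,-1.6,19.775,0.1144
male,15.0,-1.6,20.15,0.1162
male,15.5,-1.6,20.525,0.1179
male,16.0,-1.6,20.9,0.1196
male,16.5,-1.6,21.15,0.1213
male,17.0,-1.6,21.4,0.1231
male,17.5,-1.6,21.65,0.1248
male,18.0,-1.6,21.9,0.1265
male,18.5,-1.6,22.05,0.1283
male,19.0,-1.6,22.2,0.13
female,6.0,-1.4,15.2,0.09
female,6.5,-1.4,15.325,0.0912
female,7.0,-1.4,15.45,0.0923
female,7.5,-1.4,15.575,0.0935
female,8.0,-1.4,15.7,0.0946
female,8.5,-1.4,15.925,0.0958
female,9.0,-1.4,16.15,0.0969
female,9.5,-1.4,16.375,0.0981
female,10.0,-1.4,16.6,0.0992
female,10.5,-1.4,16.975,0.1004
female,11.0,-1.4,17.35,0.1015
female,11.5,-1.4,17.725,0.1027
female,12.0,-1.4,18.1,0.1038
female,12.5,-1.4,18.475,0.105
female,13.0,-1.4,18.85,0.1062
female,13.5,-1.4,19.225,0.1073
female,14.0,-1.4,19.6,0.1085
female,14.5,-1.4,19.875,0.1096
female,15.0,-1.4,20.15,0.1108
female,15.5,-1.4,20.425,0.1119
female,16.0,-1.4,20.7,0.1131
female,16.5,-1.4,20.85,0.1142
female,17.0,-1.4,21.0,0.1154
female,17.5,-1.4,21.15,0.1165
female,18.0,-1.4,21.3,0.1177
female,18.5,-1.4,21.35,0.1188
female,19.0,-1.4,21.4,0.12
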