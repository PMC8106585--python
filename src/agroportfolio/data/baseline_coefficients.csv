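land_use,npv_mean,npv_sd,payback_mean,payback_sd,food_mean,food_sd,labour_mean,labour_sd,investment_mean,investment_sd
rice,8310,1756,0,0.4,6295,1433,32,0.7,949,95
maize,8066,2643,1,1.6,9866,417,22,0.5,1073,109
pasture,3496,522,5,1.1,976,3,8,0.2,1433,142
teak_plantation,5267,2019,20,0.0,0,0,16,0.6,2184,218
alley_cropping,5690,1792,8,8.6,1551,141,12,0.4,1835,185
silvopasture,4914,696,11,2.8,814,2,14,0.4,1970,196
forest,0,0,0,0.0,0,0,0,0.0,0,0
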