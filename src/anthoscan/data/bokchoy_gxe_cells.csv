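genotype,treatment,destructive_mean,destructive_sd,hyperspectral_mean,hyperspectral_sd,rgb_pct_mean,rgb_pct_sd,n
White Stem,NC-GS1,0.880,0.023,0.423,0.027,0.30,0.20,4
White Stem,SC-GS1,0.953,0.043,0.529,0.080,0.66,0.36,4
White Stem,NC-GS2,0.378,0.030,0.603,0.051,3.01,1.11,4
White Stem,SC-GS2,0.938,0.048,0.698,0.263,1.61,0.79,4
Purple Stem,NC-GS1,6.848,0.158,1.982,0.498,17.08,10.31,4
Purple Stem,SC-GS1,9.608,0.218,8.585,1.860,53.56,11.62,4
Purple Stem,NC-GS2,5.060,0.103,4.232,0.930,54.21,11.69,4
Purple Stem,SC-GS2,10.3425,0.215,9.959,1.836,83.53,4.20,4
Red Stem,NC-GS1,1.160,0.030,0.550,0.096,0.82,0.31,4
Red Stem,SC-GS1,4.325,0.103,3.344,0.395,11.32,4.38,4
Red Stem,NC-GS2,2.045,0.070,1.766,0.678,27.53,9.44,4
Red Stem,SC-GS2,5.708,0.098,3.768,0.436,26.38,8.53,4
Green Stem,NC-GS1,0.863,0.030,0.442,0.009,0.34,0.09,4
Green Stem,SC-GS1,1.293,0.093,0.573,0.128,0.22,0.06,4
Green Stem,NC-GS2,0.663,0.030,0.620,0.060,5.64,1.88,4
Green Stem,SC-GS2,0.633,0.030,1.046,0.255,10.56,2.60,4
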