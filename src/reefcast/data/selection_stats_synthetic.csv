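# Synthetic stand-in for the supplementary per-model selection statistics
# (41 climate-model runs screened at |bias|<3 degC and seasonal-amplitude
# difference <1, strict): constructed so exactly 17 rows fail, including
# one exact-boundary bias of 3.0. Values are not transcriptions.
model_id,bias,seasonal_diff
gcm34_run1,-0.99,1.15
gcm12_run1,-1.72,0.59
gcm15_run1,-2.0,0.12
gcm24_run1,-1.21,0.19
gcm20_run1,0.26,0.6
gcm26_run1,-5.18,0.14
gcm17_run1,-2.38,0.72
gcm03_run1,-2.73,0.25
gcm41_run1,4.69,1.87
gcm11_run1,-0.92,0.83
gcm09_run1,-1.21,0.42
gcm01_run1,-0.8,0.26
gcm38_run1,1.29,1.16
gcm22_run1,-1.62,0.87
gcm36_run1,-1.6,2.57
gcm23_run1,1.27,0.9
gcm30_run1,5.95,0.46
gcm05_run1,2.13,0.22
gcm21_run1,1.15,0.38
gcm32_run1,5.5,0.83
gcm07_run1,0.69,0.72
gcm27_run1,3.37,0.54
gcm08_run1,-0.33,0.75
gcm13_run1,-2.53,0.43
gcm06_run1,-1.18,0.66
gcm39_run1,-0.7,1.46
gcm16_run1,-0.36,0.59
gcm14_run1,2.76,0.44
gcm40_run1,4.37,2.01
gcm35_run1,1.82,2.31
gcm28_run1,3.37,0.64
gcm33_run1,-3.26,0.39
gcm37_run1,-2.11,2.15
gcm10_run1,-2.19,0.6
gcm25_run1,3.0,0.4
gcm29_run1,-3.25,0.11
gcm18_run1,-0.4,0.44
gcm19_run1,-2.5,0.84
gcm31_run1,-4.72,0.67
gcm02_run1,2.68,0.67
gcm04_run1,1.79,0.11
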