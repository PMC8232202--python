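dataset,case,n_opt,RA,RAR,t_test,fisher,hellinger,relief,relieff,info_gain,gini,r_value
NPC,1,16,0.96,,0.90,0.91,0.94,0.93,0.96,0.93,0.93,0.95
TBI,1,3,0.70,,0.48,0.61,0.52,0.61,0.65,0.58,0.49,0.67
TBI,2,11,,0.89,0.80,0.81,0.78,0.82,0.87,0.79,0.72,0.83
TBI,3,1,,0.95,0.83,0.74,0.94,0.85,0.83,0.85,0.76,0.95
TBI,4,28,,0.91,0.85,0.86,0.87,0.88,0.86,0.86,0.84,0.89
TBI,5,26,,0.93,0.91,0.92,0.90,0.90,0.92,0.90,0.88,0.90
TBI,6,22,,0.77,0.65,0.68,0.69,0.73,0.74,0.73,0.50,0.71
TBI,7,25,,0.71,0.63,0.56,0.68,0.53,0.61,0.61,0.35,0.66
CHD2-1,1,10,0.60,,0.48,0.51,0.61,0.50,0.59,0.60,0.45,0.59
CHD2-1,2,11,,0.76,0.66,0.60,0.75,0.77,0.73,0.72,0.61,0.73
CHD2-1,3,6,,0.92,0.85,0.81,0.92,0.90,0.81,0.88,0.80,0.79
CHD2-1,4,31,,0.86,0.81,0.79,0.86,0.87,0.82,0.84,0.75,0.84
CHD2-1,5,37,,0.87,0.85,0.84,0.86,0.86,0.81,0.86,0.90,0.82
CHD2-1,6,11,,0.64,0.57,0.45,0.50,0.57,0.57,0.64,0.36,0.62
CHD2-1,7,10,,0.60,0.52,0.55,0.52,0.48,0.52,0.60,0.36,0.52
CHD2-2,1,3,0.60,,0.52,0.49,0.54,0.50,0.52,0.55,0.39,0.57
CHD2-2,2,34,,0.86,0.79,0.84,0.88,0.73,0.80,0.80,0.70,0.79
CHD2-2,3,14,,0.90,0.85,0.84,0.82,0.90,0.68,0.88,0.81,0.84
CHD2-2,4,24,,0.93,0.88,0.88,0.88,0.90,0.86,0.91,0.87,0.93
CHD2-2,5,28,,0.91,0.88,0.90,0.88,0.85,0.91,0.89,0.89,0.90
CHD2-2,6,7,,0.63,0.53,0.56,0.66,0.59,0.44,0.56,0.28,0.59
CHD2-2,7,4,,0.66,0.56,0.63,0.50,0.66,0.66,0.63,0.22,0.56
ATR,1,25,0.88,,0.98,0.51,0.85,0.85,0.76,0.85,0.50,0.76
ATR,2,9,,0.96,0.79,0.86,0.96,0.96,0.93,0.96,0.75,0.93
ATR,3,8,,0.97,1.00,0.90,0.97,0.90,0.97,0.97,0.80,0.93
ATR,4,2,,0.98,0.93,0.83,0.88,0.98,0.95,0.98,0.81,0.95
ATR,5,2,,0.98,0.81,0.86,0.76,0.93,0.93,0.95,0.71,0.88
ATR,6,9,,0.94,0.81,0.75,0.88,0.94,0.88,0.81,0.19,0.81
ATR,7,10,,0.94,0.81,0.63,0.69,0.63,0.94,0.88,0.19,0.75
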