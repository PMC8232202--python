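dataset,case,n_opt,RA,RAR,t_test,fisher,hellinger,relief,relieff,info_gain,gini,r_value
NPC,1,15,0.96,,0.87,0.90,0.91,0.92,0.96,0.92,0.91,0.91
TBI,1,8,0.62,,0.27,0.58,0.40,0.47,0.56,0.47,0.26,0.46
TBI,2,18,,0.85,0.79,0.81,0.78,0.86,0.84,0.81,0.65,0.75
TBI,3,1,,0.93,0.77,0.60,0.91,0.85,0.74,0.85,0.74,0.89
TBI,4,27,,0.89,0.84,0.81,0.83,0.85,0.86,0.83,0.81,0.85
TBI,5,13,,0.91,0.81,0.82,0.81,0.82,0.90,0.86,0.79,0.81
TBI,6,30,,0.78,0.61,0.69,0.64,0.62,0.66,0.67,0.50,0.70
TBI,7,24,,0.71,0.65,0.54,0.64,0.59,0.57,0.62,0.41,0.58
CHD2-1,1,10,0.61,,0.33,0.30,0.52,0.28,0.45,0.43,0.23,0.45
CHD2-1,2,11,,0.77,0.56,0.58,0.69,0.65,0.64,0.68,0.55,0.65
CHD2-1,3,6,,0.88,0.79,0.88,0.81,0.77,0.81,0.86,0.79,0.86
CHD2-1,4,31,,0.86,0.81,0.80,0.80,0.82,0.83,0.85,0.73,0.80
CHD2-1,5,37,,0.87,0.81,0.75,0.84,0.85,0.82,0.84,0.78,0.82
CHD2-1,6,11,,0.66,0.46,0.45,0.48,0.65,0.53,0.55,0.40,0.50
CHD2-1,7,10,,0.63,0.44,0.53,0.52,0.55,0.56,0.56,0.40,0.48
CHD2-2,1,3,0.45,,0.22,0.33,0.27,0.32,0.31,0.27,0.21,0.26
CHD2-2,2,34,,0.87,0.68,0.78,0.76,0.82,0.85,0.86,0.73,0.80
CHD2-2,3,14,,0.87,0.81,0.74,0.81,0.86,0.76,0.83,0.79,0.78
CHD2-2,4,24,,0.91,0.84,0.90,0.87,0.85,0.85,0.87,0.85,0.81
CHD2-2,5,28,,0.90,0.86,0.88,0.80,0.88,0.86,0.89,0.79,0.79
CHD2-2,6,7,,0.71,0.42,0.62,0.64,0.66,0.45,0.57,0.35,0.63
CHD2-2,7,4,,0.64,0.64,0.57,0.50,0.63,0.55,0.66,0.40,0.60
ATR,1,25,0.93,,0.75,0.52,0.52,0.82,0.82,0.82,0.25,0.60
ATR,2,9,,1.00,0.81,0.88,0.92,0.94,0.94,0.94,0.68,0.88
ATR,3,8,,1.00,1.00,0.78,1.00,0.88,0.93,1.00,0.82,0.88
ATR,4,2,,0.95,0.84,0.79,0.91,0.91,0.88,0.91,0.70,0.91
ATR,5,2,,0.95,0.79,0.78,0.78,0.88,0.90,0.95,0.61,0.88
ATR,6,9,,1.00,0.89,0.69,0.85,0.89,0.76,0.85,0.36,0.80
ATR,7,10,,1.00,0.61,0.54,0.64,0.54,0.80,0.89,0.37,0.80
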