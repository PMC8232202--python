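dataset,case,n_opt,RA,RAR,t_test,fisher,hellinger,relief,relieff,info_gain,gini,r_value
NPC,1,7,1.00,,0.87,0.97,0.95,0.95,0.95,0.95,1.00,0.92
TBI,1,6,0.96,,0.41,0.68,0.68,0.70,0.88,0.72,0.58,0.63
TBI,2,11,,1.00,0.84,0.88,0.95,0.90,0.94,0.86,0.90,0.90
TBI,3,1,,1.00,0.95,0.84,0.95,0.90,0.80,0.95,0.90,1.00
TBI,4,10,,1.00,0.96,1.00,0.89,0.93,0.97,0.93,0.85,1.00
TBI,5,7,,1.00,0.93,0.90,0.97,0.97,0.93,0.97,0.86,0.93
TBI,6,12,,1.00,0.75,0.83,0.82,0.83,0.91,0.85,0.71,1.00
TBI,7,29,,1.00,0.71,0.70,0.65,0.82,0.85,0.78,0.71,0.71
CHD2-1,1,10,0.87,,0.67,0.71,0.87,0.00,0.77,0.77,0.47,0.87
CHD2-1,2,11,,0.94,0.85,0.85,1.00,0.87,0.93,0.94,0.85,0.91
CHD2-1,3,6,,1.00,0.86,1.00,1.00,1.00,0.93,1.00,0.93,1.00
CHD2-1,4,31,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.95,1.00
CHD2-1,5,37,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
CHD2-1,6,11,,0.87,0.61,0.75,0.87,0.87,0.89,0.87,0.50,0.87
CHD2-1,7,10,,0.87,0.61,0.71,0.87,0.87,0.87,0.87,0.71,0.71
CHD2-2,1,3,0.58,,0.48,0.58,0.48,0.58,0.55,0.68,0.00,0.73
CHD2-2,2,34,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
CHD2-2,3,14,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
CHD2-2,4,24,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
CHD2-2,5,28,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
CHD2-2,6,7,,1.00,1.00,0.82,0.82,1.00,0.82,0.82,0.47,0.82
CHD2-2,7,4,,0.86,0.82,1.00,0.82,1.00,0.61,1.00,0.00,0.75
ATR,1,25,1.00,,1.00,1.00,1.00,1.00,1.00,1.00,0.50,1.00
ATR,2,9,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
ATR,3,8,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
ATR,4,2,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.89,1.00
ATR,5,2,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.80,1.00
ATR,6,9,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.71,1.00
ATR,7,10,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
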