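dataset,case,n_opt,RA,RAR,t_test,fisher,hellinger,relief,relieff,info_gain,gini,r_value
NPC,1,8,1.00,,0.88,0.95,0.95,0.97,1.00,0.95,0.95,0.92
TBI,1,11,0.93,,0.82,0.86,0.87,0.90,0.90,0.88,0.83,0.88
TBI,2,13,,1.00,0.84,0.90,0.94,0.95,0.94,0.84,0.87,0.86
TBI,3,1,,1.00,0.87,0.87,1.00,1.00,0.96,0.95,0.83,1.00
TBI,4,7,,1.00,0.91,0.97,0.93,0.97,0.90,0.93,0.89,1.00
TBI,5,10,,1.00,0.87,0.93,0.93,0.93,0.93,0.97,0.88,0.93
TBI,6,19,,1.00,0.73,0.80,0.86,0.86,0.77,0.80,0.71,0.91
TBI,7,11,,1.00,0.83,0.92,0.80,0.86,0.86,0.75,0.50,0.86
CHD2-1,1,10,0.88,,0.87,0.88,0.87,0.87,0.87,0.87,0.83,0.87
CHD2-1,2,11,,0.94,0.94,0.71,0.93,0.89,0.93,0.88,0.67,0.89
CHD2-1,3,6,,1.00,0.89,1.00,1.00,1.00,0.93,0.94,0.94,0.92
CHD2-1,4,31,,1.00,0.95,0.95,0.96,0.90,0.96,0.90,0.86,0.95
CHD2-1,5,37,,1.00,1.00,0.91,0.95,0.95,1.00,0.95,0.86,0.95
CHD2-1,6,11,,0.89,0.50,0.75,0.73,0.89,1.00,0.83,0.55,0.67
CHD2-1,7,10,,0.86,0.73,0.57,0.80,0.75,0.86,0.67,0.55,0.57
CHD2-2,1,3,0.91,,0.87,0.86,0.95,0.87,0.91,0.90,0.87,0.91
CHD2-2,2,34,,1.00,1.00,1.00,0.88,0.92,0.93,1.00,0.88,0.93
CHD2-2,3,14,,1.00,1.00,0.92,0.86,0.92,1.00,0.93,0.86,0.93
CHD2-2,4,24,,1.00,0.90,0.91,0.95,0.95,0.95,1.00,0.95,0.95
CHD2-2,5,28,,1.00,0.95,0.95,0.95,0.95,1.00,0.96,0.95,1.00
CHD2-2,6,7,,0.86,0.57,0.80,0.80,0.75,0.86,0.86,0.50,0.86
CHD2-2,7,4,,0.86,0.80,0.75,0.57,0.86,0.86,0.86,0.50,0.67
ATR,1,25,1.00,,1.00,0.89,1.00,1.00,1.00,1.00,0.89,1.00
ATR,2,9,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
ATR,3,8,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
ATR,4,2,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.89,1.00
ATR,5,2,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.00
ATR,6,9,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.67,1.00
ATR,7,10,,1.00,1.00,1.00,1.00,1.00,1.00,1.00,0.67,1.00
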