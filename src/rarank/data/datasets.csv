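dataset,attributes,instances,majority,minority,ratio
NPC,24,200,100,100,1.00
TBI,42,104,73,31,2.35
CHD2-1,50,72,51,21,2.43
CHD2-2,50,67,51,16,3.19
ATR,104,29,21,8,2.63
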