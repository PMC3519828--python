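time_h,dFdC,dFdC-MP,dFdC-DP,dFdC-TP,dFdU,dFdU-MP,dFdU-DP,dFdU-TP
0,0,0,0,0,0,0,0,0
4,3,7,59,121,0.08,1.12,0.68,1.34
12,1,8,53,75,0.06,1.15,0.41,0.66
24,0.1,4,35,37,0.03,0.2,0.07,0.2
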