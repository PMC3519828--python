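time_h,dFdC-out,dFdC,dFdC-MP,dFdC-DP,dFdC-TP
0,9.70E+06,0,0,0,0
4,0,1.51E+05,3.51E+05,2.96E+06,6.07E+06
12,0,5.02E+04,4.01E+05,2.66E+06,3.76E+06
24,0,5.02E+03,2.01E+05,1.76E+06,1.86E+06
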