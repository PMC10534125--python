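species,cooking,analyte,mean,median,min,max,sd
all,all,Nap,5.85,5.80,3.06,9.60,2.11
all,all,Acy,0.34,0.31,0.13,0.78,0.22
all,all,Ace,0.70,0.72,0.16,1.43,0.38
all,all,Fle,1.49,1.44,0.73,2.28,0.46
all,all,Ph,0.34,0.31,0.14,0.86,0.22
all,all,An,0.25,0.19,0.08,0.67,0.17
all,all,Fla,1.51,1.35,0.92,2.57,0.45
all,all,Py,2.08,2.00,1.43,3.10,0.46
all,all,BaA,1.31,1.22,0.76,2.08,0.37
all,all,Chr,1.14,1.06,0.68,1.79,0.32
all,all,BbF,1.31,1.22,0.77,2.05,0.39
all,all,BkF,0.80,0.84,0.24,1.33,0.29
all,all,BaP,1.08,1.00,0.61,1.89,0.36
all,all,DahA,1.34,1.27,0.67,2.12,0.43
all,all,BgP,0.32,0.25,0.25,0.64,0.14
all,all,IcdP,0.45,0.32,0.32,0.77,0.19
all,all,TOTAL,20.31,19.42,11.28,33.90,6.60
all,all,PAH4,4.85,4.58,2.88,7.81,1.40
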