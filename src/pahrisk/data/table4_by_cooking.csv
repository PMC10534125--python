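species,cooking,analyte,mean,median,min,max,sd
all,raw,Nap,4.71,4.20,3.06,6.87,1.54
all,raw,Acy,0.21,0.13,0.13,0.34,0.11
all,raw,Ace,0.60,0.65,0.16,0.98,0.33
all,raw,Fle,1.30,1.25,0.73,1.98,0.49
all,raw,Ph,0.21,0.14,0.14,0.31,0.09
all,raw,An,0.16,0.08,0.08,0.40,0.14
all,raw,Fla,1.30,1.34,0.92,1.65,0.30
all,raw,Py,1.77,1.74,1.43,2.23,0.32
all,raw,BaA,1.09,1.05,0.76,1.60,0.33
all,raw,Chr,0.92,0.95,0.68,1.24,0.22
all,raw,BbF,1.07,1.11,0.77,1.37,0.26
all,raw,BkF,0.64,0.72,0.24,0.95,0.28
all,raw,BaP,0.88,0.86,0.67,1.03,0.14
all,raw,DahA,1.02,1.00,0.67,1.38,0.27
all,raw,BgP,0.25,0.25,0.25,0.25,0.00
all,raw,IcdP,0.32,0.32,0.32,0.32,0.00
all,raw,TOTAL,16.44,15.94,11.28,22.75,4.63
all,raw,PAH4,3.96,3.96,2.88,5.24,0.92
all,charcoal_grilled,Nap,7.37,8.23,4.11,9.60,2.30
all,charcoal_grilled,Acy,0.49,0.45,0.28,0.78,0.22
all,charcoal_grilled,Ace,0.90,1.00,0.16,1.43,0.51
all,charcoal_grilled,Fle,1.67,1.68,1.03,2.28,0.50
all,charcoal_grilled,Ph,0.60,0.64,0.32,0.86,0.21
all,charcoal_grilled,An,0.40,0.40,0.18,0.67,0.19
all,charcoal_grilled,Fla,1.89,1.88,1.34,2.57,0.51
all,charcoal_grilled,Py,2.41,2.24,2.00,3.10,0.45
all,charcoal_grilled,BaA,1.63,1.63,1.19,2.08,0.35
all,charcoal_grilled,Chr,1.37,1.42,0.98,1.79,0.34
all,charcoal_grilled,BbF,1.66,1.79,1.11,2.05,0.41
all,charcoal_grilled,BkF,0.97,1.03,0.52,1.33,0.30
all,charcoal_grilled,BaP,1.31,1.20,0.89,1.89,0.39
all,charcoal_grilled,DahA,1.64,1.72,1.00,2.12,0.46
all,charcoal_grilled,BgP,0.45,0.51,0.25,0.64,0.19
all,charcoal_grilled,IcdP,0.64,0.71,0.32,0.77,0.18
all,charcoal_grilled,TOTAL,25.41,26.49,15.67,33.90,7.31
all,charcoal_grilled,PAH4,5.98,6.04,4.17,7.81,1.47
all,gas_oven_grilled,Nap,5.46,5.15,3.31,7.95,1.99
all,gas_oven_grilled,Acy,0.33,0.13,0.13,0.70,0.28
all,gas_oven_grilled,Ace,0.63,0.61,0.16,1.00,0.37
all,gas_oven_grilled,Fle,1.48,1.39,0.87,2.10,0.49
all,gas_oven_grilled,Ph,0.26,0.29,0.14,0.41,0.12
all,gas_oven_grilled,An,0.25,0.18,0.08,0.51,0.17
all,gas_oven_grilled,Fla,1.40,1.20,1.00,1.93,0.40
all,gas_oven_grilled,Py,2.03,2.00,1.62,2.47,0.30
all,gas_oven_grilled,BaA,1.20,1.13,0.83,1.62,0.30
all,gas_oven_grilled,Chr,1.12,1.03,0.76,1.61,0.31
all,gas_oven_grilled,BbF,1.23,1.09,0.87,1.86,0.39
all,gas_oven_grilled,BkF,0.78,0.80,0.45,1.18,0.30
all,gas_oven_grilled,BaP,0.98,0.76,0.61,1.59,0.40
all,gas_oven_grilled,DahA,1.34,1.25,0.98,1.76,0.33
all,gas_oven_grilled,BgP,0.25,0.25,0.25,0.25,0.00
all,gas_oven_grilled,IcdP,0.39,0.32,0.32,0.70,0.17
all,gas_oven_grilled,TOTAL,19.12,17.13,12.62,27.26,6.02
all,gas_oven_grilled,PAH4,4.53,3.98,3.22,6.68,1.38
all,fried,Nap,5.86,5.97,3.45,8.55,2.20
all,fried,Acy,0.35,0.31,0.13,0.60,0.23
all,fried,Ace,0.67,0.76,0.16,1.07,0.37
all,fried,Fle,1.50,1.48,0.92,2.09,0.46
all,fried,Ph,0.29,0.14,0.14,0.65,0.23
all,fried,An,0.19,0.19,0.08,0.35,0.12
all,fried,Fla,1.44,1.29,1.11,2.20,0.44
all,fried,Py,2.10,1.92,1.47,2.80,0.60
all,fried,BaA,1.31,1.24,0.88,1.89,0.37
all,fried,Chr,1.17,1.20,0.82,1.58,0.29
all,fried,BbF,1.27,1.20,1.00,1.79,0.30
all,fried,BkF,0.82,0.88,0.52,1.22,0.28
all,fried,BaP,1.16,1.10,0.80,1.80,0.38
all,fried,DahA,1.37,1.29,0.90,1.98,0.49
all,fried,BgP,0.32,0.25,0.25,0.60,0.16
all,fried,IcdP,0.46,0.32,0.32,0.68,0.20
all,fried,TOTAL,20.28,19.65,13.41,29.45,6.54
all,fried,PAH4,4.91,4.76,3.50,7.06,1.31
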