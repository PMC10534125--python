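species,cooking,analyte,mean,median,min,max,sd
carp,all,Nap,7.29,7.22,5.69,9.02,1.37
carp,all,Acy,0.53,0.58,0.30,0.65,0.16
carp,all,Ace,0.99,0.95,0.80,1.25,0.19
carp,all,Fle,1.79,1.80,1.56,2.00,0.18
carp,all,Ph,0.38,0.35,0.14,0.70,0.23
carp,all,An,0.31,0.29,0.19,0.48,0.12
carp,all,Fla,1.73,1.69,1.35,2.18,0.34
carp,all,Py,2.31,2.33,1.93,2.66,0.37
carp,all,BaA,1.41,1.30,1.19,1.85,0.30
carp,all,Chr,1.26,1.23,0.97,1.60,0.26
carp,all,BbF,1.45,1.31,1.20,2.00,0.37
carp,all,BkF,0.94,0.93,0.80,1.11,0.13
carp,all,BaP,1.19,1.15,0.97,1.50,0.22
carp,all,DahA,1.64,1.69,1.17,1.99,0.35
carp,all,BgP,0.43,0.43,0.25,0.60,0.20
carp,all,IcdP,0.53,0.51,0.32,0.77,0.24
carp,all,TOTAL,24.15,23.57,19.19,30.29,4.59
carp,all,PAH4,5.31,4.95,4.39,6.95,1.13
caspian_kutum,all,Nap,6.13,5.97,4.20,8.23,2.02
caspian_kutum,all,Acy,0.30,0.31,0.13,0.45,0.16
caspian_kutum,all,Ace,0.80,0.76,0.65,1.00,0.18
caspian_kutum,all,Fle,1.47,1.48,1.25,1.68,0.22
caspian_kutum,all,Ph,0.36,0.31,0.14,0.64,0.25
caspian_kutum,all,An,0.22,0.19,0.08,0.40,0.16
caspian_kutum,all,Fla,1.50,1.34,1.29,1.88,0.33
caspian_kutum,all,Py,1.88,1.74,1.65,2.24,0.32
caspian_kutum,all,BaA,1.34,1.35,1.05,1.63,0.29
caspian_kutum,all,Chr,1.19,1.20,0.95,1.42,0.24
caspian_kutum,all,BbF,1.38,1.24,1.11,1.79,0.36
caspian_kutum,all,BkF,0.88,0.88,0.72,1.03,0.16
caspian_kutum,all,BaP,1.01,0.97,0.85,1.20,0.18
caspian_kutum,all,DahA,1.34,1.29,1.00,1.72,0.36
caspian_kutum,all,BgP,0.34,0.25,0.25,0.51,0.15
caspian_kutum,all,IcdP,0.56,0.67,0.32,0.68,0.21
caspian_kutum,all,TOTAL,20.69,19.65,15.94,26.49,5.35
caspian_kutum,all,PAH4,4.92,4.76,3.96,6.04,1.05
caspian_sea_sprat,all,Nap,3.48,3.38,3.06,4.11,0.45
caspian_sea_sprat,all,Acy,0.17,0.13,0.13,0.28,0.08
caspian_sea_sprat,all,Ace,0.16,0.16,0.16,0.16,0.00
caspian_sea_sprat,all,Fle,0.89,0.90,0.73,1.03,0.12
caspian_sea_sprat,all,Ph,0.19,0.14,0.14,0.32,0.09
caspian_sea_sprat,all,An,0.13,0.13,0.08,0.18,0.06
caspian_sea_sprat,all,Fla,1.09,1.06,0.92,1.34,0.18
caspian_sea_sprat,all,Py,1.77,1.77,1.52,2.00,0.23
caspian_sea_sprat,all,BaA,0.92,0.86,0.76,1.19,0.19
caspian_sea_sprat,all,Chr,0.81,0.79,0.68,0.98,0.13
caspian_sea_sprat,all,BbF,0.94,0.94,0.77,1.11,0.15
caspian_sea_sprat,all,BkF,0.43,0.49,0.24,0.52,0.13
caspian_sea_sprat,all,BaP,0.78,0.78,0.67,0.89,0.09
caspian_sea_sprat,all,DahA,0.94,0.95,0.86,1.00,0.06
caspian_sea_sprat,all,BgP,0.25,0.25,0.25,0.25,0.00
caspian_sea_sprat,all,IcdP,0.32,0.32,0.32,0.32,0.00
caspian_sea_sprat,all,TOTAL,13.24,13.01,11.28,15.67,1.84
caspian_sea_sprat,all,PAH4,3.44,3.36,2.88,4.17,0.55
starry_sturgeon,all,Nap,8.24,8.25,6.87,9.60,1.14
starry_sturgeon,all,Acy,0.60,0.63,0.34,0.78,0.19
starry_sturgeon,all,Ace,1.12,1.04,0.98,1.43,0.21
starry_sturgeon,all,Fle,2.11,2.10,1.98,2.28,0.12
starry_sturgeon,all,Ph,0.56,0.53,0.30,0.86,0.25
starry_sturgeon,all,An,0.48,0.46,0.35,0.67,0.14
starry_sturgeon,all,Fla,2.05,2.07,1.51,2.57,0.45
starry_sturgeon,all,Py,2.65,2.64,2.23,3.10,0.38
starry_sturgeon,all,BaA,1.80,1.76,1.60,2.08,0.23
starry_sturgeon,all,Chr,1.56,1.60,1.24,1.79,0.23
starry_sturgeon,all,BbF,1.77,1.83,1.37,2.05,0.29
starry_sturgeon,all,BkF,1.17,1.20,0.95,1.33,0.16
starry_sturgeon,all,BaP,1.58,1.70,1.03,1.89,0.39
starry_sturgeon,all,DahA,1.81,1.87,1.38,2.12,0.32
starry_sturgeon,all,BgP,0.35,0.25,0.25,0.64,0.20
starry_sturgeon,all,IcdP,0.50,0.49,0.32,0.71,0.22
starry_sturgeon,all,TOTAL,28.34,28.35,22.75,33.90,4.64
starry_sturgeon,all,PAH4,6.70,6.87,5.24,7.81,1.08
trout,all,Nap,4.36,3.89,3.75,5.90,1.03
trout,all,Acy,0.18,0.13,0.13,0.31,0.09
trout,all,Ace,0.48,0.43,0.40,0.67,0.13
trout,all,Fle,1.19,1.22,1.00,1.34,0.14
trout,all,Ph,0.22,0.14,0.14,0.47,0.17
trout,all,An,0.15,0.12,0.08,0.28,0.10
trout,all,Fla,1.23,1.20,1.06,1.47,0.17
trout,all,Py,1.75,1.74,1.43,2.10,0.35
trout,all,BaA,1.15,1.17,0.86,1.41,0.23
trout,all,Chr,0.95,0.98,0.77,1.08,0.13
trout,all,BbF,1.11,1.11,0.85,1.36,0.21
trout,all,BkF,0.62,0.55,0.49,0.88,0.18
trout,all,BaP,0.95,0.98,0.76,1.10,0.17
trout,all,DahA,1.02,1.01,0.67,1.38,0.30
trout,all,BgP,0.25,0.25,0.25,0.25,0.00
trout,all,IcdP,0.42,0.32,0.32,0.72,0.20
trout,all,TOTAL,16.02,15.17,13.05,20.71,3.28
trout,all,PAH4,4.16,4.19,3.34,4.94,0.67
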