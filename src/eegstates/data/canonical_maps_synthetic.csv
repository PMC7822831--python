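class,Fp1,AF3,AF7,F1,F3,F5,F7,FC1,FC3,FC5,C1,C3,C5,FT7,T7,TP7,CP5,P5,CP1,CP3,P1,P3,PO3,PO7,P7,O1,Fp2,AF4,AF8,F2,F4,F6,F8,FC2,FC4,FC6,C2,C4,C6,FT8,T8,TP8,CP6,P6,CP2,CP4,P2,P4,PO4,PO8,P8,O2,Fz,CPz,Pz,POz,Oz,FT9,FT10,TP9,TP10,PO9,PO10
A,0.001332,0.053564,-0.060791,0.106021,0.028295,-0.050119,-0.110360,0.036827,-0.038337,-0.105858,-0.056866,-0.115505,-0.153720,-0.143539,-0.157511,-0.156567,-0.177029,-0.173106,-0.127161,-0.165148,-0.156936,-0.176567,-0.151405,-0.129400,-0.146316,-0.106542,0.107716,0.181182,0.138906,0.209428,0.219583,0.201121,0.162186,0.160520,0.191388,0.193800,0.066506,0.116141,0.148138,0.170688,0.157640,0.126399,0.091268,0.033538,-0.016675,0.039900,-0.070210,-0.016983,-0.046656,0.029319,0.080583,-0.024622,0.168391,-0.077099,-0.121179,-0.118978,-0.077092,-0.142542,0.130405,-0.117929,0.137824,-0.074897,0.075039
B,0.109038,0.180427,0.140464,0.208765,0.221534,0.204218,0.164277,0.159163,0.191310,0.195027,0.064293,0.113741,0.146821,0.172531,0.158709,0.127426,0.088161,0.033622,-0.020605,0.035632,-0.074680,-0.020176,-0.046391,0.029900,0.081342,-0.023882,0.002294,0.052058,-0.059853,0.102488,0.025243,-0.052826,-0.109385,0.037320,-0.038705,-0.104691,-0.057991,-0.115081,-0.151830,-0.142040,-0.156750,-0.156205,-0.175588,-0.172420,-0.128789,-0.164446,-0.157904,-0.176457,-0.150014,-0.129087,-0.146073,-0.106019,0.168541,-0.076941,-0.120796,-0.118300,-0.076104,0.132297,-0.141821,0.139905,-0.117331,0.076665,-0.074034
C,0.201655,0.237992,0.167518,0.165034,0.190349,0.187828,0.120782,0.049712,0.103397,0.126756,-0.043257,0.015054,0.049532,0.060662,-0.003856,-0.059028,-0.021018,-0.079005,-0.091309,-0.047700,-0.112236,-0.089440,-0.120559,-0.135649,-0.104607,-0.152449,0.200509,0.235471,0.165632,0.166911,0.191083,0.183464,0.118561,0.051534,0.104172,0.125387,-0.041627,0.017230,0.050491,0.060753,-0.003212,-0.059036,-0.018665,-0.079373,-0.089141,-0.044965,-0.110613,-0.087727,-0.121378,-0.135702,-0.104577,-0.152556,0.152769,-0.110730,-0.122361,-0.128836,-0.154283,-0.075633,-0.077754,-0.156623,-0.157369,-0.203755,-0.204212
D,-0.006575,-0.006357,-0.026989,0.160634,0.044617,-0.057577,-0.060505,0.277087,0.095589,-0.076155,0.293842,0.101879,-0.087208,-0.097668,-0.126353,-0.140187,-0.100591,-0.113161,0.211466,0.056211,0.075396,-0.018660,-0.090593,-0.142416,-0.144571,-0.137413,-0.005541,-0.005182,-0.025321,0.153574,0.037581,-0.057833,-0.058201,0.273356,0.090729,-0.075000,0.288639,0.095443,-0.087708,-0.095145,-0.124965,-0.139932,-0.101354,-0.113523,0.205193,0.050674,0.076658,-0.018696,-0.092458,-0.142729,-0.144783,-0.137594,0.206377,0.270295,0.112924,-0.043838,-0.131689,0.048621,0.048882,-0.032589,-0.034129,-0.086956,-0.087523
E,0.007734,0.001824,-0.006880,-0.019275,0.005621,0.012295,-0.033279,0.034289,0.050218,0.030858,0.124682,0.114849,0.053185,-0.068031,-0.098418,-0.114819,0.056108,0.036884,0.188808,0.152128,0.189956,0.137316,0.065227,-0.101352,-0.114278,-0.078335,0.007233,0.001207,-0.007628,-0.018675,0.005277,0.010436,-0.034032,0.032559,0.048123,0.028282,0.123189,0.111088,0.049367,-0.067161,-0.097314,-0.114072,0.053004,0.035592,0.186369,0.147540,0.188888,0.135904,0.062107,-0.101202,-0.113731,-0.078236,-0.031251,0.197049,0.204992,0.121402,-0.049137,-0.216364,-0.217117,-0.306094,-0.305135,-0.310009,-0.309768
F,0.056077,-0.013204,0.112777,0.007299,0.013350,0.057594,0.162439,0.060514,0.043601,0.066677,0.044305,0.017934,0.026107,0.173231,0.123440,0.038693,-0.048632,-0.130364,-0.037542,-0.058687,-0.145153,-0.148928,-0.213191,-0.147569,-0.062271,-0.207380,0.056252,-0.011618,0.112727,0.006291,0.013669,0.061017,0.162184,0.059319,0.042913,0.067341,0.043240,0.017875,0.028832,0.172732,0.124529,0.039148,-0.043628,-0.129805,-0.038096,-0.056728,-0.141375,-0.145340,-0.213889,-0.147313,-0.061859,-0.207496,0.008518,-0.027692,-0.140337,-0.227630,-0.233453,0.337736,0.336892,0.192172,0.189154,-0.018194,-0.019207
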