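participant_id,session,sias_km,fma_ue,mas_elbow,mlc,lmsjr
P1,initial,2,15,1,4.36,11.13
P2,initial,2,21,1+,3.90,10.48
P3,initial,2,22,1+,3.68,7.52
P4,initial,2,33,1,4.26,
P5,initial,2,30,1,3.99,10.47
P6,initial,3,17,2,4.33,9.58
P7,initial,3,32,1+,5.11,7.66
P8,initial,3,36,3,5.12,8.29
P9,initial,3,31,1,4.50,8.48
P10,initial,4,,,5.10,7.20
P11,initial,4,50,2,4.73,8.03
P12,initial,4,48,1,5.57,6.02
P13,initial,4,51,1,5.11,5.73
H1,initial,5,54,0,5.74,6.37
P1,final,2,19,0,4.41,10.08
P2,final,2,27,1,4.29,9.57
P3,final,3,30,1,4.13,8.49
P4,final,3,37,1,4.61,
P5,final,3,39,1,3.71,10.69
P6,final,3,28,1,4.49,8.27
P7,final,3,45,1,4.66,9.46
P8,final,3,43,1+,4.91,7.58
P9,final,3,35,0,5.06,7.48
P10,final,4,,,4.93,7.93
P11,final,4,50,1+,4.63,8.52
P12,final,4,52,0,5.54,5.43
P13,final,4,53,0,5.21,5.86
H1,final,5,54,0,5.80,5.69
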