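compound_id,S,Tor,MP,NRB,repul,eta,pIC50_obs,split
1,3.1684,5.3358,1221.15,9,4588.56,0.073775,7.31,train
2,2.5717,5.4927,1161.91,9,3983.94,0.07366,6.76,train
3,3.3203,14.4563,1169.66,9,4127.68,0.073705,6.75,test
4,2.8648,9.6019,1177.41,9,4278.85,0.07379,6.6,test
5,2.7726,7.3625,1173.18,10,4108.0,0.073775,6.75,train
6,2.9858,5.9475,1151.51,11,4317.95,0.07381,6.45,train
7,2.8589,2.9396,1112.51,8,3916.85,0.073545,7.43,train
8,3.0643,10.8436,1153.71,8,4206.83,0.073795,6.97,train
9,3.1563,5.5693,1218.04,8,4538.53,0.07348,7.56,train
10,3.1966,4.904,1182.3,8,4727.18,0.073045,7.05,train
11,3.2185,6.2351,1176.76,8,4381.84,0.07354,7.32,train
12,3.0551,1.8107,1255.22,8,4373.21,0.07362,7.65,test
13,3.1579,10.1711,1262.97,8,4577.86,0.07402,7.2,train
14,3.2615,5.4632,1269.28,8,4745.28,0.07349,8.0,train
15,3.3069,1.8001,1197.45,8,4532.35,0.073545,7.69,train
16,3.4701,2.1641,1208.72,9,4693.53,0.073535,7.87,train
17,3.6827,5.3083,1249.2,10,5007.98,0.073535,7.33,train
18,3.8117,8.632,1253.43,9,5170.85,0.07361,7.11,train
19,3.4844,2.1634,1269.54,10,4852.38,0.073495,7.64,train
20,3.1592,7.4478,1221.15,9,4625.67,0.074505,7.38,train
21,2.85,5.3534,1112.51,8,3894.38,0.074075,6.98,test
22,3.5298,6.5685,1178.79,11,4544.13,0.07395,6.87,train
23,3.238,13.2614,1221.56,9,4502.94,0.074275,6.77,train
24,3.138,8.0742,1218.04,8,4512.91,0.074175,7.86,test
25,3.208,8.7184,1176.76,8,4336.63,0.07393,7.21,train
26,3.0406,4.2684,1255.22,8,4340.67,0.0742,8.06,train
27,3.1589,12.5753,1262.97,8,4539.71,0.07494,7.54,train
28,3.2619,7.7031,1269.28,8,4756.57,0.07437,7.79,train
29,3.298,4.2607,1197.45,8,4524.05,0.07441,7.83,test
30,3.4583,4.5979,1208.72,9,4691.05,0.074435,7.45,train
31,3.491,4.4959,1269.54,10,4849.24,0.074305,7.44,train
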