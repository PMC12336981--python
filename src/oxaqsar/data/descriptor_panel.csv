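compound_id,S,B,S_B,Tor,LogP,NHBA,NHBD,NRB,MP,TD,MV,IR,ST,E_HOMO,E_LUMO,repul,eta,pIC50_obs,starred
1,3.17,26.86,0.57,5.34,3.12,11,2,9,1221.15,21,434.9,1.645,72,-0.1961,-0.0486,4588.56,0.07378,7.31,0
2,2.57,26.23,0.32,5.49,3.47,10,2,9,1161.91,18,380.6,1.657,75.2,-0.1966,-0.0493,3983.94,0.07366,6.76,0
3,3.32,41.93,-0.61,14.46,3.89,10,2,9,1169.66,19,396.6,1.649,73.3,-0.1964,-0.049,4127.68,0.07371,6.75,1
4,2.86,27.88,0.26,9.6,4.3,10,2,9,1177.41,19,412.7,1.643,71.7,-0.1961,-0.0485,4278.85,0.07379,6.6,1
5,2.77,27.24,0.16,7.36,3.9,10,2,10,1173.18,19,416.7,1.62,60.2,-0.1883,-0.0408,4108,0.07378,6.75,0
6,2.99,27.4,0.53,5.95,4.8,10,2,11,1151.51,19,453.8,1.589,54,-0.196,-0.0483,4317.95,0.07381,6.45,0
7,2.86,26.19,0.5,2.94,3.55,10,1,8,1112.51,17,402.4,1.609,57.9,-0.1964,-0.0493,3916.85,0.07355,7.43,0
8,3.62,25.48,0.73,8.41,3.55,11,1,11,1178.79,20,459.1,1.599,56.1,-0.1965,-0.0487,4466.09,0.0739,7.93,0
9,3.06,28.26,0.32,10.84,3.87,10,1,8,1153.71,18,414.4,1.624,61.5,-0.1955,-0.0479,4206.83,0.0738,6.97,0
10,3.25,29.82,0.42,10.76,3.33,11,2,9,1221.56,19,433,1.622,62.2,-0.1956,-0.0481,4533.19,0.07375,7.65,0
11,3.16,26.83,0.58,5.57,2.98,11,2,8,1218.04,20,429.2,1.629,64.4,-0.1962,-0.0492,4538.53,0.07348,7.56,0
12,3.2,26.39,0.57,4.9,4.46,12,1,8,1182.3,20,421,1.629,69.5,-0.1987,-0.0526,4727.18,0.07305,7.05,1
13,3.22,28.09,0.7,6.24,3.15,11,1,8,1176.76,19,423.2,1.616,60.7,-0.1969,-0.0498,4381.84,0.07354,7.32,0
14,3.06,26.23,0.53,1.81,2.93,11,2,8,1255.22,19,428.2,1.616,59.4,-0.1962,-0.0489,4373.21,0.07362,7.65,0
15,3.16,31.59,0.79,10.17,3.03,11,2,8,1262.97,19,445.9,1.608,57.7,-0.1944,-0.0464,4577.86,0.07402,7.2,0
16,3.26,28.25,0.63,5.46,3.57,11,2,8,1269.28,19,468.2,1.595,53.3,-0.1966,-0.0496,4745.28,0.07349,8.0,0
17,3.31,26.82,0.64,1.8,3.31,11,1,8,1197.45,20,443.2,1.615,58.8,-0.1965,-0.0494,4532.35,0.07355,7.69,0
18,3.47,27.34,0.69,2.16,3.64,11,1,9,1208.72,21,460.8,1.607,57.2,-0.1964,-0.0493,4693.53,0.07354,7.87,0
19,3.68,29.28,0.48,5.31,4.03,11,1,10,1249.2,22,470.1,1.626,61.4,-0.1959,-0.0488,5007.98,0.07354,7.33,0
20,3.81,29.57,0.62,8.63,4.44,11,1,9,1253.43,22,485.6,1.622,60.8,-0.1963,-0.049,5170.85,0.07361,7.11,0
21,3.48,27.74,0.71,2.16,2.79,12,2,10,1269.54,22,458.3,1.619,61.6,-0.1969,-0.0499,4852.38,0.0735,7.64,1
22,3.16,29.95,0.51,7.45,4.23,11,2,9,1221.15,21,434.9,1.645,72,-0.194,-0.045,4625.67,0.07451,7.38,0
23,2.85,29.07,0.44,5.35,4.66,10,1,8,1112.51,17,402.4,1.609,57.9,-0.1936,-0.0454,3894.38,0.07408,6.98,0
24,3.53,31.73,0.78,6.57,4.66,11,1,11,1178.79,20,459.1,1.599,56.1,-0.1937,-0.0458,4544.13,0.07395,6.87,1
25,3.24,32.64,0.36,13.26,4.44,11,2,9,1221.56,19,433,1.622,62.2,-0.1937,-0.0451,4502.94,0.07428,6.77,0
26,3.14,29.69,0.52,8.07,4.09,11,2,8,1218.04,20,429.2,1.629,64.4,-0.1933,-0.0449,4512.91,0.07418,7.86,0
27,3.21,30.93,0.64,8.72,4.26,11,1,8,1176.76,19,423.2,1.616,60.7,-0.1944,-0.0466,4336.63,0.07393,7.21,1
28,3.04,29.1,0.47,4.27,4.04,11,2,8,1255.22,19,428.2,1.616,59.4,-0.1935,-0.0451,4340.67,0.0742,8.06,0
29,3.16,34.41,0.73,12.58,4.14,11,2,8,1262.97,19,445.9,1.608,57.7,-0.1915,-0.0417,4539.71,0.07494,7.54,1
30,3.26,31.32,0.59,7.7,4.67,11,2,8,1269.28,19,468.2,1.595,53.3,-0.1937,-0.045,4756.57,0.07437,7.79,0
31,3.3,29.72,0.58,4.26,4.42,11,1,8,1197.45,20,443.2,1.615,58.8,-0.1934,-0.0446,4524.05,0.07441,7.83,0
32,3.46,30.25,0.64,4.6,4.75,11,1,9,1208.72,21,460.8,1.607,57.2,-0.1934,-0.0445,4691.05,0.07444,7.45,0
33,3.49,30.73,0.66,4.5,3.9,12,2,10,1269.54,22,458.3,1.619,61.6,-0.1937,-0.0451,4849.24,0.07431,7.44,0
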