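compound_id,mlr_pred,mlr_resid,mnlr_pred,mnlr_resid
1,7.324,-0.011,7.345,-0.032
2,6.944,-0.18,6.793,-0.028
3,6.668,0.082,6.829,-0.08
4,6.677,-0.073,6.618,-0.014
5,6.683,0.069,6.721,0.031
6,6.43,0.019,6.436,0.012
7,7.37,0.058,7.425,0.004
8,6.877,0.097,6.875,0.1
9,7.5,0.056,7.521,0.035
10,7.118,-0.063,7.195,-0.14
11,7.371,-0.056,7.417,-0.102
12,8.17,-0.518,8.148,-0.497
13,7.44,-0.238,7.399,-0.197
14,7.748,0.248,7.78,0.216
15,7.852,-0.159,7.772,-0.08
16,7.641,0.225,7.602,0.265
17,7.274,0.058,7.284,0.048
18,7.218,-0.106,7.124,-0.012
19,7.658,-0.014,7.709,-0.065
20,7.231,0.152,7.256,0.127
21,7.263,-0.287,7.312,-0.337
22,6.821,0.053,6.827,0.048
23,6.829,-0.055,6.811,-0.037
24,7.412,0.45,7.359,0.502
25,7.25,-0.041,7.26,-0.05
26,8.073,-0.01,8.074,-0.011
27,7.43,0.11,7.494,0.047
28,7.703,0.088,7.672,0.119
29,7.793,0.034,7.725,0.102
30,7.584,-0.134,7.552,-0.102
31,7.608,-0.167,7.635,-0.194
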