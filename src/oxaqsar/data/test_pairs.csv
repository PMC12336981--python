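compound_id,pIC50_obs,pIC50_pred_mlr,residual
3,6.75,6.668,0.082
4,6.604,6.677,-0.073
12,7.652,8.17,-0.518
21,6.976,7.263,-0.287
24,7.862,7.412,0.45
29,7.827,7.793,0.034
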