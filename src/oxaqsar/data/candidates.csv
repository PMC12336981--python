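compound_id,S,Tor,MP,NRB,repul,eta,pIC50_pred_published
M1,2.3184,10.7868,1106.02,6,3659.74,0.08601,9.28
M2,2.281,12.669,1166.25,6,3579.79,0.086,9.53
M3,2.4091,10.8049,1116.7,6,3640.16,0.08575,9.38
M4,2.3513,10.94,1106.02,6,3690.36,0.08685,9.42
M5,2.3358,11.5044,1166.25,6,3647.79,0.08576,9.58
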