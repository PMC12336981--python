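candidate_id,TPSA,n_rotatable,MW,LogP,n_HBA,n_HBD,lipinski_reported,veber_reported,egan_reported,muegge_reported,synthetic_accessibility,ames_toxicity
M1,115.55,6,473.55,3.98,9,2,yes,yes,yes,yes,5.12,no
M2,135.78,6,471.56,3.47,9,3,yes,yes,yes,yes,5.09,no
M3,115.55,6,469.58,3.98,8,2,yes,yes,yes,yes,5.15,no
M4,115.55,6,473.55,3.8,9,2,yes,yes,yes,yes,5.12,no
M5,135.78,6,471.56,3.83,9,2,yes,yes,yes,yes,5.09,no
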