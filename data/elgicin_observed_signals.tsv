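peptide_id	mz	z
elgicin_AI	1512.89	3
elgicin_AI	1135.07	4
elgicin_AII	1532.58	3
elgicin_AII	1149.31	4
elgicin_B	1569.89	3
elgicin_B	1177.72	4
elgicin_C	1608.30	3
elgicin_C	1206.14	4
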