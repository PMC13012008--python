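tf	rank	gene	r
NEUROD1	1	NEUROD1_TGT01	1.0
NEUROD1	2	NEUROD1_TGT02	1.0
ASCL1	1	ASCL1_TGT01	1.0
ASCL1	2	ASCL1_TGT02	1.0
POU2F3	1	POU2F3_TGT02	1.0
POU2F3	2	POU2F3_TGT01	1.0
YAP1	1	YAP1_TGT01	1.0
YAP1	2	YAP1_TGT02	1.0
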