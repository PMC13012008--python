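sample_id	Y_sig
S001	-0.442175
S002	-0.339144
S003	-0.545206
S004	-0.39066
S005	-0.493691
S006	-0.287629
S007	-0.339144
S008	-0.442175
S009	-0.545206
S010	2.185118
S011	2.082087
S012	-0.442175
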