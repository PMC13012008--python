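sample_id	label	provenance	tie_broken	zN	zA	zP	zY
S001	A	tf_relaxed	False	-0.670726	1.467588	-0.566184	-0.442175
S002	A	tf_relaxed	False	-0.587319	1.553706	-0.477371	-0.339144
S003	A	tf_relaxed	False	-0.754132	1.381471	-0.654997	-0.545206
S004	N	tf_relaxed	False	1.456135	-0.642294	-0.521777	-0.39066
S005	N	tf_relaxed	False	1.372729	-0.728412	-0.610591	-0.493691
S006	N	tf_relaxed	False	1.539542	-0.556177	-0.432964	-0.287629
S007	P	tf_relaxed	False	-0.587319	-0.599235	1.742958	-0.339144
S008	P	tf_relaxed	False	-0.670726	-0.685353	1.654145	-0.442175
S009	P	tf_relaxed	False	-0.754132	-0.771471	1.565332	-0.545206
S010	Y	tf_relaxed	False	-0.629023	-0.642294	-0.521777	2.185118
S011	Y	tf_relaxed	False	-0.712429	-0.728412	-0.610591	2.082087
S012	N	tf_relaxed	False	0.997401	0.950882	-0.566184	-0.442175
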