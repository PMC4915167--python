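trait_1	trait_2	chrom	start_mb	end_mb	peak_mb_1	peak_mb_2
CSm	CS	1	0.413	0.884	3.408620	0.575063
CSm	CS	6	12.391	12.937	15.164578	12.391211
PO	CS	19	60.053	60.141	60.369264	60.140763
CSm	CS	25	13.798	14.530	16.085565	14.223691
CSm	CS	27	27.775	27.877	27.790463	27.813590
US	MY	4	44.177	44.917	44.260073	44.198598
WWm	US	6	88.485	88.959	88.958116	88.922396
US	MY	6	88.485	88.959	88.922396	88.919352
WWm	MY	6	88.485	89.223	88.958116	88.919352
WWm	US	8	60.296	61.521	60.762241	61.044151
US	MY	8	60.348	60.353	61.044151	60.352572
WWm	MY	8	60.348	60.353	60.762241	60.352572
WWm	US	18	33.562	34.342	33.031008	34.538807
WWm	US	19	61.166	61.845	60.504374	61.534509
WWm	MY	20	5.554	7.327	6.392965	5.504819
WWm	MY	20	57.350	59.102	58.801089	58.162729
US	MY	28	43.511	44.630	43.242413	44.036312
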