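trait	chrom	start_mb	end_mb	peak_mb	peak_logbf
PO	6	38.287	39.552	38.955154	12.5
CSm	11	70.279	73.525	72.949696	12.2
CS	21	39.493	40.269	39.668783	12.9
CS	27	27.504	27.877	27.813590	16.3
CSm	28	15.064	15.531	15.458787	13.6
US	6	88.485	88.959	88.922396	16.3
MY	5	28.577	29.137	29.072132	13.4
MY	6	88.485	89.223	88.919352	14.4
MY	10	69.747	72.705	70.306697	12.8
MY	13	82.728	84.013	83.805618	12.1
MY	20	3.861	7.327	5.504819	13.2
MY	27	42.375	43.266	42.896895	13.4
WWm	7	24.793	25.722	25.004920	13.9
WWm	28	19.766	20.801	19.922560	14.6
WWm	28	29.412	29.772	29.570491	12.1
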