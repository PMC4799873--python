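# Xq28 microsatellite marker map flanking the F8 c.6046C>T mutation.
# Physical positions in Mb; recombination fractions to the mutation are
# derived downstream via 1 Mb ~ 1 cM (theta = |Mb distance| * 0.01).
name	xq_band	position_mb	repeat_unit	allele_min_bp	allele_max_bp	role
DXS7423	Xq28	149.71	TCCA	175	199	marker
DXS1073	Xq28	153.82	TG	120	146	marker
STR24	Xq28	154.07	GT	178	196	marker
STR22	Xq28	154.10	GT	198	210	marker
c.6046C>T	Xq28	154.13	NA	NA	NA	mutation
STR13	Xq28	154.16	TG	148	164	marker
DXS1108	Xq28	154.86	CA	160	177	marker
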