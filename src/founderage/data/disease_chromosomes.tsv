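# Disease cohort: one hemizygous X chromosome per unrelated hemophilia A family,
# all carrying the F8 c.6046C>T mutation. Markers in map order.
sample_id	family_id	group	DXS7423	DXS1073	STR24	STR22	STR13	DXS1108
P01	F01	disease	189	128	190	206	156	171
P02	F02	disease	189	128	190	206	156	171
P03	F03	disease	189	128	190	206	156	171
P04	F04	disease	189	128	190	206	156	171
P05	F05	disease	189	128	190	206	156	171
P06	F06	disease	189	128	190	206	156	171
P07	F07	disease	189	128	190	206	156	171
P08	F08	disease	189	128	190	206	156	171
P09	F09	disease	189	128	190	206	156	171
P10	F10	disease	189	128	190	206	156	171
P11	F11	disease	189	128	190	206	156	171
P12	F12	disease	189	128	190	206	156	171
P13	F13	disease	189	128	190	206	156	171
P14	F14	disease	189	128	190	206	156	171
P15	F15	disease	189	128	190	206	156	171
P16	F16	disease	189	128	190	206	156	171
P17	F17	disease	189	128	190	206	156	171
P18	F18	disease	185	128	190	206	156	171
P19	F19	disease	185	128	190	206	156	171
P20	F20	disease	185	128	190	206	156	171
P21	F21	disease	185	128	190	206	156	171
P22	F22	disease	177	130	190	206	156	171
P23	F23	disease	189	142	196	204	158	171
P24	F24	disease	181	144	194	204	154	161
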