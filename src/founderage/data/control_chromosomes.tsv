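# SYNTHETIC control cohort: 96 hemizygous control chromosomes.
# Full control haplotypes were not published; this table is a deterministic
# expansion consistent with the reported per-marker control allele counts
# (189:15/96, 128:16/96, 190:80/96, 206:63/96, 156:48/96, 171:29/96) and
# with zero carriage of any disease-associated haplotype H1-H5.
sample_id	family_id	group	DXS7423	DXS1073	STR24	STR22	STR13	DXS1108
C01	CF01	control	189	128	190	206	156	165
C02	CF02	control	189	128	190	206	156	165
C03	CF03	control	189	128	190	206	156	165
C04	CF04	control	189	128	190	206	156	165
C05	CF05	control	189	128	190	206	156	165
C06	CF06	control	189	128	190	206	156	165
C07	CF07	control	189	128	190	206	156	165
C08	CF08	control	189	128	190	206	156	165
C09	CF09	control	189	128	190	206	156	165
C10	CF10	control	189	128	190	206	156	165
C11	CF11	control	189	128	190	206	156	165
C12	CF12	control	189	128	190	206	156	165
C13	CF13	control	189	128	190	206	156	165
C14	CF14	control	189	128	190	206	156	165
C15	CF15	control	189	128	190	206	156	165
C16	CF16	control	179	128	190	206	156	165
C17	CF17	control	179	132	190	206	156	165
C18	CF18	control	179	132	190	206	156	165
C19	CF19	control	179	132	190	206	156	165
C20	CF20	control	179	132	190	206	156	165
C21	CF21	control	179	132	190	206	156	165
C22	CF22	control	179	132	190	206	156	165
C23	CF23	control	179	132	190	206	156	165
C24	CF24	control	179	132	190	206	156	165
C25	CF25	control	179	132	190	206	156	165
C26	CF26	control	179	132	190	206	156	165
C27	CF27	control	179	132	190	206	156	165
C28	CF28	control	179	132	190	206	156	165
C29	CF29	control	179	132	190	206	156	165
C30	CF30	control	179	132	190	206	156	165
C31	CF31	control	179	132	190	206	156	165
C32	CF32	control	179	132	190	206	156	165
C33	CF33	control	179	132	190	206	156	165
C34	CF34	control	179	132	190	206	156	165
C35	CF35	control	179	132	190	206	156	165
C36	CF36	control	179	132	190	206	156	165
C37	CF37	control	179	132	190	206	156	165
C38	CF38	control	179	132	190	206	156	165
C39	CF39	control	179	132	190	206	156	165
C40	CF40	control	179	132	190	206	156	165
C41	CF41	control	179	132	190	206	156	165
C42	CF42	control	179	132	190	206	156	167
C43	CF43	control	179	132	190	206	156	167
C44	CF44	control	179	132	190	206	156	167
C45	CF45	control	179	132	190	206	156	167
C46	CF46	control	179	132	190	206	156	167
C47	CF47	control	179	132	190	206	156	167
C48	CF48	control	179	132	190	206	156	167
C49	CF49	control	179	132	190	206	160	167
C50	CF50	control	179	132	190	206	160	167
C51	CF51	control	179	132	190	206	160	167
C52	CF52	control	179	132	190	206	160	167
C53	CF53	control	179	132	190	206	160	167
C54	CF54	control	179	132	190	206	160	167
C55	CF55	control	179	132	190	206	160	167
C56	CF56	control	179	132	190	206	160	167
C57	CF57	control	183	132	190	206	160	167
C58	CF58	control	183	132	190	206	160	167
C59	CF59	control	183	132	190	206	160	167
C60	CF60	control	183	132	190	206	160	167
C61	CF61	control	183	132	190	206	160	167
C62	CF62	control	183	136	190	206	160	167
C63	CF63	control	183	136	190	206	160	167
C64	CF64	control	183	136	190	208	160	167
C65	CF65	control	183	136	190	208	160	167
C66	CF66	control	183	136	190	208	160	167
C67	CF67	control	183	136	190	208	160	167
C68	CF68	control	183	136	190	208	160	171
C69	CF69	control	183	136	190	208	160	171
C70	CF70	control	183	136	190	208	160	171
C71	CF71	control	183	136	190	208	160	171
C72	CF72	control	183	136	190	208	160	171
C73	CF73	control	183	136	190	208	160	171
C74	CF74	control	183	136	190	208	160	171
C75	CF75	control	183	136	190	208	160	171
C76	CF76	control	183	136	190	208	160	171
C77	CF77	control	183	136	190	208	162	171
C78	CF78	control	183	136	190	208	162	171
C79	CF79	control	183	136	190	208	162	171
C80	CF80	control	183	136	190	208	162	171
C81	CF81	control	183	136	192	208	162	171
C82	CF82	control	183	136	192	210	162	171
C83	CF83	control	183	136	192	210	162	171
C84	CF84	control	183	136	192	210	162	171
C85	CF85	control	183	136	192	210	162	171
C86	CF86	control	183	136	192	210	162	171
C87	CF87	control	183	136	192	210	162	171
C88	CF88	control	183	136	192	210	162	171
C89	CF89	control	183	136	192	210	162	171
C90	CF90	control	183	136	192	210	162	171
C91	CF91	control	183	136	188	210	162	171
C92	CF92	control	183	136	188	210	162	171
C93	CF93	control	183	136	188	210	162	171
C94	CF94	control	183	136	188	210	162	171
C95	CF95	control	183	136	188	210	162	171
C96	CF96	control	183	136	188	210	162	171
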