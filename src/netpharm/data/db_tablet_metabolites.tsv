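metabolite_id	parent_id	parent_name	score	reliability	reaction_site	reaction_type	enzyme
M1	3	3,5,4'-trihydroxyStilbene	0.94	0.86	3	Aromatic Hydroxylation	CYP1A2
M1	3	3,5,4'-trihydroxyStilbene	0.94	0.86	7	Aromatic Hydroxylation	CYP1A2
M2	3	3,5,4'-trihydroxyStilbene	0.65	0.87	14	Aromatic Hydroxylation	CYP1A2
M3	4	4'-methoxy-3'7-dihydroxyflavan	0.92	0.78	21	O-dealkylation	CYP1A2
M4	5	7,4'-Dihydroxyflavan	0.92	0.79	13	Aromatic Hydroxylation	CYP1A2
M4	5	7,4'-Dihydroxyflavan	0.92	0.79	15	Aromatic Hydroxylation	CYP1A2
M5	25	3,4-Dihydroxy-allylbenzene	0.85	0.74	4	Aliphatic Hydroxylation	CYP2C19
M5	25	3,4-Dihydroxy-allylbenzene	0.91	0.86	4	Aliphatic Hydroxylation	CYP2C9
M6	27	Loureirin B	0.74	0.5	18	Aromatic Hydroxylation	CYP1A2
M6	27	Loureirin B	0.74	0.5	19	Aromatic Hydroxylation	CYP1A2
M7	28	pterostilbene	0.90	0.74	10	Aromatic Hydroxylation	CYP1A2
M7	28	pterostilbene	0.90	0.74	13	Aromatic Hydroxylation	CYP1A2
M8	37	Diosgenin	0.64	0.52	24	Aliphatic Hydroxylation	CYP3A4
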