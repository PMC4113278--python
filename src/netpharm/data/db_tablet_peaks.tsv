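no	rt	mz_measured	mz_expected	delta_ppm	polarity	formula	name	papp	previously_reported
1	8.11	311.11395	311.11363	1.046	negative	C15H20O7	3,4-dihydroxyallylbenzene 4-O—D-Glucopyranoside	3.8494	yes
2	8.38	285.07592	285.07575	0.594	positive	C16H12O5	unknown		no
2	8.38	283.06137	283.0612	0.606	negative	C16H12O5
3	8.68	229.08608	229.08592	0.702	positive	C14H12O3	3,5,4'-trihydroxystilbene	148.9186	yes
3	8.68	227.07154	227.07137	0.752	negative	C14H12O3
4	8.68	273.07713	273.07685	1.054	negative	C15H14O5	4'-methoxy-3'7-dihydroxyflavan	115.6472	yes
5	8.72	255.06525	255.06519	0.241	positive	C15H10O4	7,4'-dihydroxyflavan	137.4393	yes
5	8.72	253.05074	253.05063	0.408	negative	C15H10O4
6	8.74	259.09663	259.09649	0.563	positive	C15H14O4	2,4,4'-Trihydroxydihydrochalcone	94.5322	yes
6	8.74	257.08211	257.08193	0.707	negative	C15H14O4
7	8.83	314.13891	314.13868	0.703	positive	C18H19NO4	norisoboldine	30.448	yes
7	8.83	312.12448	312.12413	1.11	negative	C18H19NO4
8	9.27	149.06084	149.0608	0.219	negative	C9H10O2	unknown		no
9	9.66	269.08209	269.08193	0.594	negative	C16H14O4	unknown		no
10	9.78	525.19107	525.19078	0.558	positive	C32H28O7	dracaenin A	134.7937	yes
10	9.78	523.1766	523.17623	0.709	negative	C32H28O7
11	10.02	273.11223	273.11214	0.359	positive	C16H16O4	unknown		no
11	10.02	271.09769	271.09758	0.385	negative	C16H16O4
12	10.21	303.1228	303.1227	0.339	positive	C17H18O5	unknown		no
12	10.21	301.10831	301.10815	0.531	negative	C17H18O5
13	10.21	392.20704	392.20676	0.696	positive	C21H26O6	3,4-O-dimethylcedrusin	149.4172	yes
14	10.21	167.0704	167.07027	0.788	positive	C9H10O3	Ethyl 4-hydroxybenzoate	216.6625	yes
15	10.57	287.09152	287.0914	0.414	positive	C16H14O5	unknown		no
15	10.57	285.07703	285.07685	0.638	negative	C16H14O5
16	10.73	532.23343	532.23298	0.849	positive	C31H30O7	cochinchinenin	21.059	yes
16	10.73	513.19218	513.19188	0.587	negative	C31H30O7
17	10.95	301.10837	301.10815	0.733	negative	C17H18O5	unknown		no
18	11.2	241.08608	241.08592	0.665	positive	C15H12O3	(2S)-7-hydroxyflavanone	227.3156	yes
18	11.2	239.07151	239.07137	0.616	negative	C15H12O3
19	11.45	199.07646	199.07645	0.057	negative	C13H12O2	4,4'-Dihydroxydiphenylmethane	201.7499	yes
20	11.64	529.22251	529.22208	0.817	positive	C32H32O7	unknown		no
20	11.64	527.20758	527.20753	0.102	negative	C32H32O7
21	11.65	511.21352	511.21261	1.776	negative	C32H32O6	homoisosocotrin-4-ol	17.1673	yes
22	11.86	283.09773	283.09758	0.507	negative	C17H16O4	unknown		no
23	12	516.23823	516.23806	0.321	positive	C31H30O6	socotrin 4-ol	7.5670	yes
24	12.13	287.12781	287.12779	0.077	positive	C17H18O4	Loureirin A	228.3831	yes
24	12.13	285.11337	285.11323	0.492	negative	C17H18O4
25	12.13	151.07542	151.07536	0.442	positive	C9H10O2	3,4-Dihydroxy-allylbenzene	140.4007	yes
26	12.23	227.10674	227.10666	0.351	positive	C15H14O2	7-hydroxyflavanone	227.3156	yes
27	12.23	317.13839	317.13835	0.136	positive	C18H20O5	Loureirin B	227.8266	yes
27	12.23	315.12406	315.1238	0.833	negative	C18H20O5
28	12.93	257.11728	257.11722	0.227	positive	C16H16O3	pterostilbene	236.2931	yes
28	12.93	255.10277	255.10267	0.396	negative	C16H16O3
29	13	885.45033	885.44894	1.572	negative	C44H70O18	26-O—D-Glucopynanosyl-furostan-5,25(27)-diene-1,3,22,26-tetrol-1-O-[-L-rhamnopyranosyl(12)]—L-Arabinopyranoside	0.0073	yes
30	13.25	167.0704	167.07027	0.799	positive	C9H10O3	unknown		no
31	14.08	265.14798			negative		unknown		no
32	14.39	462.32139	462.3214	-0.029	positive	C27H40O5	dracaenol B	141.9713	yes
33	14.90	571.23383			negative		unknown		no
34	14.91	527.24323	527.24282	0.786	positive	C33H34O6	cochinchinenin E	8.2809	yes
35	15.77	532.92554			negative		unknown		no
36	15.92	325.18451	325.18569	-3.642	negative	C14H29O8	unknown		no
37	16.27	415.32104	415.32067	0.894	positive	C27H42O3	Diosgenin	112.3202	yes
38	16.44	325.18448	325.18569	-3.734	negative	C14H29O8	unknown		no
39	17.44	339.20010	339.20134	-3.668	negative	C15H31O8	unknown		no
40	19.18	698.91071			negative		unknown		no
41	19.95	323.25817	323.25807	0.292	positive	C20H34O3	bincatriol	172.7858	yes
42	20.25	445.29987			negative		unknown		no
43	20.49	628.19489			positive		unknown		no
44	20.63	383.18988	383.19117	-4.807	negative	C16H31O10	unknown		no
45	21	461.32938			positive		unknown		no
46	21.6	116.92857			negative		unknown		no
47	22.14	394.3465	394.34415	4.577	positive	C25H46O3	unknown		no
48	24.99	427.3939	427.39344	1.082	positive	C30H50O	lupeol	0.0386	yes
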