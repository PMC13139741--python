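item	label	M	O	A	I	R	Q
1	Intelligent emotion monitoring	282	235	725	322	2	5
2	Professional psychology courses	235	672	246	413	3	2
3	Professional psychology online counseling	258	626	229	453	4	1
4	Professional psychology testing	151	582	307	527	3	1
5	Psychological test result analysis	654	209	471	220	10	7
6	Recommended psychological knowledge	599	279	246	434	8	5
7	Psychology articles/educational videos	699	272	291	301	5	3
8	Offline psychological counseling	680	122	493	269	5	2
9	Mindfulness practice	224	130	667	541	7	2
10	Emotional regulation training	661	285	375	245	4	1
11	Stress relief games	202	628	272	458	7	4
12	Gratitude practice	131	223	640	573	1	3
13	Muscle relaxation training	188	267	597	512	6	1
14	Mental journaling	131	102	714	608	10	6
15	Light music	240	563	217	537	5	9
16	White noise	148	534	433	454	1	1
17	Psychological radio station	159	185	418	804	2	3
18	Personal data recording	680	272	344	266	7	2
19	User privacy and security protection	319	640	251	351	6	4
20	Nurse confession	223	494	460	388	4	2
21	Voice sharing	608	213	356	387	6	1
22	AI interaction	281	150	488	643	6	3
23	Check-in reward system	298	215	397	652	5	4
24	Health monitoring	205	243	663	454	4	2
25	Program customization	558	184	494	330	4	1
26	Live-streaming training	162	126	645	631	3	4
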