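SNP	CHR	POS	EA	OA	EAF	BETA	SE	P	F
rs6691964	1	55433978	A	G	0.092472	-0.0234719	0.00358388	5.80E-11	40.74048769
rs556369867	1	55491135	T	C	0.330585	0.0175746	0.00243048	4.80E-13	60.23211898
rs72909541	1	55494301	T	C	0.046097	-0.0334061	0.00501479	2.70E-11	43.24046364
rs150119739	1	55520938	A	G	0.045318	0.0452728	0.00520209	3.20E-18	78.14487409
rs7525503	1	55522558	T	G	0.02036	0.0454642	0.0075822	2.00E-09	36.32774896
rs11587071	1	55522674	T	C	0.168881	-0.0282322	0.00279415	5.30E-24	98.59387078
rs10493176	1	55538552	G	T	0.07579	-0.0531381	0.00394676	2.60E-41	174.3354587
rs3976734	1	55489960	G	A	0.374504	-0.0297494	0.00231882	1.10E-37	182.7413453
rs200730299	1	55491853	C	A	0.195034	-0.0543492	0.00278155	5.10E-85	408.9747062
rs17192725	1	55496131	A	G	0.095408	0.0305717	0.00365832	6.40E-17	71.08305236
rs17111503	1	55503448	G	A	0.268141	0.0406795	0.00235743	1.00E-66	286.3144736
rs7546522	1	55516713	T	C	0.155442	-0.0168117	0.00295297	1.20E-08	32.6943445
rs2483205	1	55518316	T	C	0.438633	-0.0295845	0.00214514	2.90E-43	189.9691892
rs11583974	1	55551718	A	G	0.042146	0.0314531	0.00517068	1.20E-09	35.19140196
rs56349475	1	55576102	C	T	0.024601	-0.0475957	0.00671909	1.40E-12	47.90016489
rs79396670	1	55588142	A	G	0.035496	-0.0336489	0.00562029	2.10E-09	34.15687648
rs146273942	1	55453841	A	G	0.023188	-0.0538858	0.00722418	8.70E-14	57.95612818
rs2479420	1	55492190	T	C	0.73803	-0.0283879	0.0023826	9.90E-33	137.3240966
rs11810371	1	55496861	A	G	0.043743	-0.0294547	0.00507333	6.40E-09	31.97740435
rs11591147	1	55505647	T	G	0.017468	-0.348456	0.00793088	1.00E-200	1843.821775
rs11206513	1	55507649	T	C	0.600617	0.0316517	0.0021463	3.20E-49	211.8406735
rs11206517	1	55526428	G	T	0.033149	0.0680285	0.00580615	1.00E-31	130.7253793
rs2495517	1	55448842	G	A	0.794271	0.0177548	0.0025792	5.80E-12	45.38996213
rs12732125	1	55470153	T	C	0.020368	-0.10344	0.0073736	1.00E-44	188.1885252
rs2479395	1	55484582	C	T	0.668453	0.0125674	0.00221762	1.50E-08	30.84299521
rs77875082	1	55485042	A	G	0.032388	0.0481535	0.00605559	1.80E-15	64.03589791
rs41294821	1	55513183	T	C	0.022807	-0.0386615	0.00705365	4.20E-08	29.35311066
rs472495	1	55521313	T	G	0.648959	0.0425743	0.00218093	7.30E-85	364.1230994
rs530804537	1	55583210	A	G	0.011303	-0.192336	0.00997554	7.80E-83	364.5495945
rs55637835	1	55466303	T	C	0.120881	-0.0187129	0.00324835	8.40E-09	32.78985634
rs12739979	1	55496648	T	C	0.246521	-0.0202563	0.00254032	1.50E-15	67.16311122
rs72660548	1	55500978	G	C	0.018458	0.0509816	0.00777535	5.50E-11	41.49355463
rs45613943	1	55518622	C	T	0.048725	-0.0340702	0.0048672	2.60E-12	47.41036718
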