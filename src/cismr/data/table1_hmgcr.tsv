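SNP	CHR	POS	EA	OA	EAF	BETA	SE	P	F
rs75240579	5	74624484	T	C	0.048363	-0.0372115	0.00487202	2.20E-14	56.15824795
rs2006760	5	74562029	G	C	0.205486	0.03556	0.00261075	3.00E-42	181.9725737
rs62366588	5	74664987	A	C	0.065948	-0.0271295	0.00433093	3.70E-10	39.94982959
rs141642272	5	74615209	C	G	0.026705	0.0532822	0.00653971	3.70E-16	65.02565811
rs55727654	5	74651864	A	G	0.14871	0.042154	0.0029315	6.90E-47	198.2942
rs111353455	5	74623949	A	G	0.085844	0.0243909	0.00372718	6.00E-11	41.13824406
rs2303152	5	74641707	A	G	0.101442	0.0333589	0.00345272	4.40E-22	89.39119883
rs116153450	5	74729433	A	C	0.04623	-0.0303618	0.00499242	1.20E-09	35.81600769
rs12916	5	74656539	C	T	0.400537	0.0621175	0.00212705	1.70E-187	817.8199832
rs17562727	5	74682474	C	T	0.027617	0.0394972	0.00635898	5.30E-10	36.91493872
rs80324692	5	74717761	T	C	0.081157	-0.0260509	0.00385694	1.40E-11	44.59395641
rs115845757	5	74563700	A	G	0.019	0.048608	0.00785612	6.10E-10	38.80571168
rs17648121	5	74650106	T	C	0.029877	0.0619849	0.00619367	1.40E-23	98.14125847
rs140092661	5	74682600	T	A	0.034128	0.0329927	0.00582168	1.50E-08	31.61670332
rs12659331	5	74757657	C	A	0.054326	0.0251785	0.00459392	4.20E-08	28.69831922
rs72633963	5	74630829	A	G	0.1238	0.0564278	0.00316653	4.90E-71	304.5296074
rs10051965	5	74560487	T	C	0.369925	0.0410063	0.00216518	5.40E-80	345.5945975
rs35122945	5	74610293	C	A	0.067368	-0.0281057	0.00423755	3.30E-11	43.73359482
rs4703665	5	74602898	C	T	0.848709	0.0244938	0.00297742	1.90E-16	67.88447107
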