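SNP	CHR	POS	EA	OA	EAF	BETA	SE	P	F
rs2173997	7	44592091	T	C	0.443739	-0.0213142	0.00211012	5.50E-24	98.8236711
rs73107478	7	44596644	C	A	0.079159	0.0259282	0.00392582	4.00E-11	43.18088467
rs11763759	7	44570067	C	T	0.303527	-0.0133498	0.00234076	1.20E-08	33.19732916
rs2073547	7	44582331	G	A	0.184007	0.0355498	0.00267287	2.30E-40	167.2550498
rs148825701	7	44559803	T	C	0.212133	0.017365	0.00256025	1.20E-11	44.4092852
rs12666108	7	44586578	C	T	0.091516	0.0249436	0.00363876	7.10E-12	45.58235923
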