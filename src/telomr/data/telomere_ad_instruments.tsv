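SNP	Chr	BP	Gene	A1	A2	Freq_TL	Freq_AD	Beta_TL	SE_TL	P_TL	Beta_AD	SE_AD	P_AD	Removed
rs10936599	3	169774313	TERC	C	T	0.76	0.75	1.00E-01	1.10E-02	3.00E-31	-7.83E-04	2.42E-03	7.46E-01	No
rs8105767	19	22032639	ZNF208	G	A	0.25	0.30	6.40E-02	1.10E-02	1.11E-09	-3.39E-04	2.31E-03	8.83E-01	No
rs11125529	2	54248729	ACYP2	A	C	0.16	0.13	6.50E-02	1.20E-02	8.00E-10	-3.65E-03	3.14E-03	2.46E-01	No
rs4387287	10	103918139	OBFC1	A	C	0.14	0.19	1.20E-01	1.30E-02	2.00E-11	-7.81E-03	2.69E-03	3.66E-03	No
rs2736100	5	1286401	TERT	C	A	0.52	0.50	8.50E-02	1.30E-02	4.38E-19	-3.98E-03	2.10E-03	5.85E-02	No
rs3027234	17	8232774	CTC1	C	T	0.83	0.79	1.03E-01	1.20E-02	2.00E-08	1.54E-03	2.57E-03	5.48E-01	No
rs755017	20	63790269	ZBTB46	G	A	0.17	0.13	1.90E-02	1.29E-02	6.71E-09	-2.58E-03	3.14E-03	4.13E-01	No
rs7675998	4	163086668	NAF1	G	A	0.80	0.78	4.80E-02	1.20E-02	4.35E-16	-1.97E-03	2.53E-03	4.38E-01	No
rs6028466	20	39500359	DHX35	A	G	0.17	0.06	5.80E-02	1.30E-02	2.57E-08	-5.65E-04	4.43E-03	8.98E-01	No
rs6772228	3	58390292	PXK	T	A	0.87	0.96	4.10E-02	1.40E-02	3.91E-10	4.28E-03	5.34E-03	4.23E-01	No
rs1317082	3	169779797	TERC	A	G	0.71	0.75	9.70E-02	1.10E-02	1.00E-08	-8.53E-04	2.42E-03	7.25E-01	Yes
rs412658	19	22176638	ZNF676	T	C	0.35	0.36	8.60E-02	1.00E-02	1.00E-08	-1.08E-03	2.19E-03	6.20E-01	Yes
rs12696304	3	169763483	TERC	C	G	0.74	0.71	9.00E-02	1.10E-02	4.00E-14	-6.68E-04	2.31E-03	7.73E-01	Yes
rs9419958	10	103916188	OBFC1	T	C	0.13	0.16	1.29E-01	1.30E-02	9.00E-11	-8.91E-03	2.91E-03	2.19E-03	Yes
rs9420907	10	103916707	OBFC1	C	A	0.14	0.15	1.42E-01	1.40E-02	7.00E-11	-9.18E-03	2.91E-03	1.59E-03	Yes
rs10936601	3	169810661	TERC	C	T	0.74	0.71	8.70E-02	1.10E-02	4.00E-15	-7.62E-04	2.32E-03	7.42E-01	Yes
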