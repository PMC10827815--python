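name	unit_length	abundance_pct	total_bp	n_copies	divergence_pct	at_pct	sf	divpeak	rps	distribution
TaeSat01-584	584	0.4729	80175466	137287	9.82	37.33		4	45.61	Dispersed
TaeSat02-118	118	0.3053	51760562	438649	12.53	48.31		12	43.09	Multiple locations
TaeSat03-2619	2619	0.2757	46742178	17847	22.57	63.38		24	41.02	Terminal
TaeSat04-337	337	0.2710	45945340	136336	8.13	65.28	SF-1	2	41.97	Multiple locations
TaeSat05-500	500	0.2204	37366616	74733	24.02	56.80	SF-2	21	29.58	Dispersed
TaeSat06-403	403	0.1815	30771510	76356	21.85	60.55		21	30.45	Dispersed
TaeSat07-343	343	0.1688	28618352	83435	6.67	59.18	SF-1	2	43.37	Multiple locations
TaeSat08-663	663	0.1066	18072964	27259	7.11	65.16	SF-3	4	55.98	Terminal
TaeSat09-335	335	0.1003	17004862	50761	9.72	36.12	SF-4	7	41.69	Multiple locations
TaeSat10-206	206	0.0892	15122968	73412	5.79	65.62	SF-1	2	53.46	Multiple locations
TaeSat11-506	506	0.0784	13291936	26269	12.44	62.85	SF-2	7	43.94	Dispersed
TaeSat12-369	369	0.0460	7798840	21135	5.08	60.16	SF-5	2	68.40	Terminal
TaeSat13-44	44	0.0348	5899992	134091	7.61	70.45		7	46.99	Multiple locations
TaeSat14-1463	1463	0.0261	4424994	3025	18.25	59.13	SF-6	23	20.60	(peri)centromeric
TaeSat15-620	620	0.0260	4408040	7110	24.66	62.58		29	26.89	Multiple locations
TaeSat16-567	567	0.0199	3373846	5950	11.61	53.62	SF-5	4	35.83	(peri)centromeric
TaeSat17-323	323	0.0143	2424422	7506	8.90	62.23		7	54.80	Terminal
TaeSat18-733	733	0.0121	2051434	2799	7.92	66.58		4	48.83	Multiple locations
TaeSat19-653	653	0.0111	1881894	2882	17.70	54.52	SF-3	2	40.24	Multiple locations
TaeSat20-322	322	0.0096	1627584	5055	15.74	39.75	SF-4	4	25.59	Terminal
TaeSat21-1590	1590	0.0091	1542814	970	6.59	35.60		2	55.99	Dispersed
TaeSat22-320	320	0.0079	1339366	4186	8.79	48.12	SF-6	7	42.83	Terminal
TaeSat23-319	319	0.0075	1271550	3986	10.82	42.01	SF-6	4	39.36	Terminal
TaeSat24-338	338	0.0069	1169826	3461	13.38	40.83		5	26.83	Multiple locations
TaeSat25-318	318	0.0048	813792	2559	15.95	45.60	SF-6	12	20.87	Multiple locations
TaeSat26-210	210	0.0045	762930	3633	3.24	59.52		0	80.40	Terminal
TaeSat27-72	72	0.0044	745976	10361	8.29	50.00		4	43.68	Terminal
TaeSat28-543	543	0.0040	678160	1249	10.78	55.43		5	42.92	(peri)centromeric
TaeSat29-319	319	0.0035	593390	1860	10.39	47.02	SF-6	2	37.69	Multiple locations
TaeSat30-1389	1389	0.0032	542528	391	13.73	63.43		2	31.23	Multiple locations
TaeSat31-889	889	0.0029	491666	553	2.80	59.39		2	91.49	(peri)centromeric
TaeSat32-528	528	0.0019	322126	610	2.37	56.63		0	90.80	Terminal
TaeSat33-54	54	0.0006	101724	1884	22.04	72.22		19	42.69	Multiple locations
TaeSat34-175	175	0.0004	67816	388	16.21	70.69		18	26.46	Multiple locations
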