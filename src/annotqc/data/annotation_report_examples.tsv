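# Published annotation-report example rows for complete prokaryotic genomes
# (two well-annotated model organisms plus per-column extreme cases).
# Columns: bioproject, organism, replicons, length_mbp, gc_percent, proteins,
# rnas, trna_aa, hypothetical, coding_density, avg_protein_len_aa,
# min_protein_len_aa, short_protein_percent, standard_start_percent
bioproject	organism	replicons	length_mbp	gc_percent	proteins	rnas	trna_aa	hypothetical	coding_density	avg_protein_len_aa	min_protein_len_aa	short_protein_percent	standard_start_percent
225	Escherichia coli str. K-12 substr. MG1655	1	4.640	50.79	4144	175	22	21	0.89	316	14	20.32	90.54
76	Bacillus subtilis subsp. subtilis str. 168	1	4.216	43.51	4177	178	20	221	0.99	294	20	26.48	77.76
17977	Candidatus Carsonella ruddii PV	1	0.160	16.56	182	31	20	44	1.14	274	37	32.42	96.15
32135	Candidatus Hodgkinia cicadicola Dsem	1	0.144	58.39	169	18	12	37	1.18	257	38	33.73	27.22
46847	Streptomyces bingchenggensis BCW-1	1	11.937	70.75	10022	84	21	3606	0.84	342	24	19.86	60.69
19943	Rickettsia rickettsii str. Iowa	1	1.268	32.45	1384	37	19	607	1.09	232	17	47.76	73.55
81	Clostridium tetani E88	1	2.799	28.75	2373	72	20	247	0.85	336	101	12.09	68.27
12634	Anaeromyxobacter dehalogenans 2CP-C	1	5.013	74.91	4346	58	21	965	0.87	349	38	15.85	69.21
49535	Propionibacterium freudenreichii subsp. shermanii CIRM-BIA1	1	2.616	67.27	2375	51	20	721	0.91	317	2	21.14	70.57
43535	Lactobacillus salivarius CECT 5713	1	1.828	32.94	1350	120	21	86	0.74	352	95	2.22	80.00
105	Haloarcula marismortui ATCC 43049	2	3.420	61.93	3412	59	20	1	1.00	285	30	27.02	100.00
13128	Photobacterium profundum SS9	2	6.323	41.71	5413	209	21	2490	0.86	316	35	21.97	73.88
28711	Haliangium ochraceum DSM 14365	1	9.446	69.48	6719	55	20	1827	0.71	411	32	13.37	79.67
244	Nostoc sp. PCC 7120	1	6.414	41.35	5368	64	20	0	0.84	326	17	25.58	82.41
19857	Vibrio harveyi ATCC BAA-1116	2	5.969	45.44	5944	159	20	5944	1.00	286	24	30.43	84.84
28111	Sorangium cellulosum 'So ce 56'	1	13.034	71.38	9375	319	0	4170	0.72	401	30	13.08	73.33
344	Rhizobium leguminosarum bv. viciae 3841	1	5.057	61.09	4700	0	0	247	0.93	309	40	19.57	80.83
31271	Mycobacterium leprae Br4923	1	3.268	57.80	1604	47	20	143	0.49	335	33	21.01	54.30
29335	Neisseria gonorrhoeae NCCP11945	1	2.232	52.37	2662	67	20	324	1.19	240	32	41.81	71.22
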