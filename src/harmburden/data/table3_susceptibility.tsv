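gene	distance	FC	p	p_adj	ensembl_id	chromosome	sfari_score	syndromic	n_reports
ARHGEF2	5.65E-08	1.54E+01	8.49E-05	1.00E-02	ENSG00000116584	1	3	0	7
CNTN5	8.69E-08	3.65E+01	1.49E-09	3.49E-07	ENSG00000149972	11	2	0	11
CSMD1	8.19E-08	3.25E+01	1.19E-08	2.51E-06	ENSG00000183117	8	2	0	19
CTNND2	8.53E-08	3.52E+01	2.96E-09	6.49E-07	ENSG00000169862	5	2	0	15
DMD	6.58E-08	2.09E+01	4.72E-06	7.46E-04	ENSG00000198947	X	S	1	46
HS3ST5	5.19E-08	1.30E+01	3.06E-04	3.17E-02	ENSG00000249853	6	2	0	8
IL1RAPL1	5.83E-08	1.65E+01	4.94E-05	6.39E-03	ENSG00000169306	X	2	0	27
ITGA8	6.48E-08	2.03E+01	6.48E-06	9.81E-04	ENSG00000077943	10	3	0	7
KCNC2	6.07E-08	1.79E+01	2.37E-05	3.27E-03	ENSG00000166006	12	3	0	13
KIRREL3	1.53E-07	1.14E+02	1.32E-26	1.42E-23	ENSG00000149571	11	2	0	19
LRFN5	7.54E-08	2.75E+01	1.57E-07	2.81E-05	ENSG00000165379	14	2	0	7
NFIB	8.87E-08	3.81E+01	6.59E-10	1.65E-07	ENSG00000147862	9	2	1	7
NLGN1	1.08E-07	5.60E+01	7.09E-14	2.82E-11	ENSG00000169760	3	2	0	21
NXPH1	2.26E-07	2.47E+02	1.10E-55	2.96E-52	ENSG00000122584	7	2	0	6
PBX1	1.01E-07	4.92E+01	2.28E-12	7.90E-10	ENSG00000185630	1	2	0	8
RORA	9.68E-08	4.54E+01	1.62E-11	5.29E-09	ENSG00000069667	15	S	1	25
SLC24A2	9.66E-08	4.52E+01	1.78E-11	5.61E-09	ENSG00000155886	9	2	0	4
SLITRK5	5.98E-08	1.73E+01	3.16E-05	4.19E-03	ENSG00000165300	13	2	0	10
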