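gene	LumA	LumB	Her2	Basal	Normal
ACTR3B	-0.7819	-0.6901	-0.1117	0.9399	0.3018
ANLN	-0.6775	0.4736	0.4568	0.5218	-1.0577
BAG1	0.9321	0.5071	-0.3966	-1.0633	-0.2396
BCL2	0.7223	0.5777	-0.5851	-0.9380	0.2518
BIRC5	-0.6281	0.6146	0.4702	0.7430	-0.9321
BLVRA	0.6263	0.4748	-0.5700	-0.8995	0.1961
CCNB1	-0.6588	0.7563	0.4968	0.9143	-1.1873
CCNE1	-0.8134	0.6693	0.2699	0.6423	-0.9836
CDC20	-0.6793	0.6901	0.3425	0.8958	-0.8169
CDC6	-0.8864	0.6741	0.4485	0.8066	-0.9134
CDH3	-0.6197	-0.2259	-0.2090	0.8452	0.6095
CENPF	-0.7943	0.4920	0.4328	0.6947	-1.0000
CEP55	-0.7198	0.7745	0.2466	0.6960	-1.0196
CXXC5	0.7555	0.5603	-0.2496	-0.8606	0.0630
EGFR	-0.6091	-0.6341	0.0330	1.1578	0.4250
ERBB2	-0.2634	0.1404	0.7827	-0.3839	-0.5123
ESR1	0.9070	0.2931	-0.4350	-0.8936	0.1448
EXO1	-0.5835	0.8137	0.3649	0.8799	-1.1515
FGFR4	-0.3795	0.3109	0.8045	-0.1017	-0.2398
FOXA1	0.9539	0.3084	-0.3678	-0.8378	0.1430
FOXC1	-0.6146	-0.6994	0.0310	1.2282	0.6287
GPR160	0.7784	0.7150	-0.3289	-0.9420	0.4041
GRB7	-0.1506	0.0270	0.8665	-0.4556	-0.9302
KIF2C	-0.9939	0.8717	0.2221	0.9655	-0.8028
KRT14	-0.6567	-0.4108	-0.3093	0.9973	0.2487
KRT17	-0.8133	-0.8938	-0.0765	0.9047	0.5554
KRT5	-0.5593	-0.2548	-0.3598	0.9928	0.5751
MAPT	0.8597	0.6356	-0.1724	-1.0321	0.1712
MDM2	0.7353	0.4503	-0.4262	-0.6947	0.1625
MELK	-0.8213	0.5646	0.4425	0.8531	-1.0821
MIA	-0.6397	-0.3829	-0.4047	1.1175	0.2977
MKI67	-0.9368	0.3012	0.2120	0.6094	-0.9057
MLPH	0.6235	0.6223	-0.5429	-0.9197	0.2590
MMP11	0.1884	0.0537	0.3912	-0.0249	-0.6964
MYBL2	-0.6859	0.6201	0.2360	0.8031	-1.0313
MYC	-0.0503	0.2472	0.2965	0.7983	-0.3741
NAT1	0.6478	0.5973	-0.4770	-0.9536	-0.0042
NDC80	-0.8046	0.6961	0.2822	0.7429	-0.5541
NUF2	-1.0231	0.5406	0.4599	0.7799	-0.7357
ORC6	-0.8636	0.7921	0.6363	0.8160	-0.8583
PGR	1.0228	0.4498	-0.5097	-0.9419	-0.0194
PHGDH	-0.5024	-0.4990	-0.2531	1.2669	0.4618
PTTG1	-0.8959	0.6097	0.5071	1.1294	-1.0114
RRM2	-0.7410	0.5491	0.4559	0.8087	-0.9570
SFRP1	-0.4965	-0.5227	0.0110	0.6506	0.5344
SLC39A6	0.8490	0.5064	-0.2111	-0.7778	0.2590
TMEM45B	-0.2848	0.0282	0.7609	-0.4400	-0.3780
TYMS	-1.1779	0.4475	0.2344	0.5641	-0.8144
UBE2C	-0.6922	0.5018	0.7185	0.7825	-0.9103
UBE2T	-1.0757	0.6220	0.5179	0.7687	-0.8500
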