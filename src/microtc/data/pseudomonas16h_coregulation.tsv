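tc_name	classification	n_genes	n_overlap	op_printed	cc	ri_printed
24 hr Pseudomonas infection	Pathogen infection	477	277	64	0.982917	0.623816
Leaf, WT, Golovinomyces orontii infection for 5 d vs. 0 d control	Pathogen infection	716	241	43	0.93683	0.385622
BTH Effect for 8 hr in wrky18 mutant	Plant defense elicitor	1245	296	36	0.943639	0.3242
BTH Effect for 8 hr in WT	Plant defense elicitor	1614	308	30	0.951557	0.279581
SA effect at 6 hr (Col-0)	Plant defense elicitor	421	121	30	0.954483	0.274902
Pseudomonas syringae pv tomato DC3000 hrcC-infiltration for 24 hr	Pathogen infection	1065	223	30	0.939357	0.272162
BTH treatment in mil4 mutant vs. H2O in mil4 mutant	Plant defense elicitor	652	184	35	0.872943	0.271469
BTH Effect for 24 hr in wrky18 mutant	Plant defense elicitor	1655	307	30	0.935343	0.263835
Leaf, eds16, Golovinomyces orontii infection for 5 d vs. WT, infection for 5 d	Plant defense related mutant	495	169	38	-0.82538	0.26286
siz1-3 mutant vs. Col-0 WT	Plant defense related mutant	987	221	32	0.889254	0.255498
mil4 overexpression line with BTH treatment vs. mil4 overexpression line control	Plant defense elicitor	574	181	37	0.820014	0.254887
SA effects at 4 hr (MT-0)	Plant defense elicitor	702	158	29	0.934091	0.254588
BTH Effect for 24 hr in WT	Plant defense elicitor	2062	341	27	0.94732	0.250527
pmr5 pmr6 double mutant vs. WT	Plant defense related mutant	423	126	31	0.892795	0.249832
Leaf, WT, Golovinomyces orontii infection for 7 d vs. 0 d control	Pathogen infection	2111	329	26	0.940966	0.23379
BTH treatment in WT vs. WT control	Plant defense elicitor	496	141	32	0.847156	0.230768
120 hr Erysiphe orontii infection	Pathogen infection	591	159	32	0.837777	0.229624
Whole plant, mkk2, 24 h BTH vs. mkk2 control	Plant defense elicitor	973	225	33	0.828929	0.228364
SA effect at 4 hr (Est)	Plant defense elicitor	259	78	24	0.96622	0.22756
PsmES4326 infection for 9 hr	Pathogen infection	340	99	27	0.90638	0.225606
Phytophthora infection for 24 hr	Pathogen infection	776	152	26	0.919965	0.222373
Pseudomonas syringae pv phaseolicola infiltration for 24 hr	Pathogen infection	1667	256	25	0.93104	0.216709
upf3 mutant vs WT	Others	635	123	24	0.938378	0.213205
Whole plant, WT, 24 h BTH vs. WT control	Plant defense elicitor	707	165	30	0.834236	0.211088
Pst DC3118 COR-hrpS double mutant infection 10 hr	Pathogen infection	418	90	22	0.963317	0.209057
Ozone effects	Plant defense elicitor	1544	247	25	0.898834	0.207327
SA effect at 4 hr (Tsu-1)	Plant defense elicitor	294	83	24	0.911413	0.204284
cpr5scv1 double mutant	Plant defense related mutant	742	163	29	0.833698	0.20177
Leaf, eds16 mutant, Golovinomyces orontii infection for 7 d vs. eds16 mutant, 0 d control	Pathogen infection	2644	341	22	0.939944	0.199188
Phytophthora infection for 12 hr	Pathogen infection	877	152	24	0.907767	0.199132
shoot under Caesium treatment	Others	187	64	22	0.938556	0.19851
E. coli TUV86-2 fliC mutant infection 7 hr	Pathogen infection	859	136	21	0.941937	0.194622
Whole plant, mkk1, 24 h BTH vs. mkk1 control	Plant defense elicitor	1003	176	25	0.867235	0.191285
SA effects at 4 hr (Van-0)	Plant defense elicitor	243	66	21	0.938173	0.18619
Pst DC3000 hrpA mutant infection 7 hr	Pathogen infection	796	121	20	0.947091	0.184426
siz1-3 mutant drought with treatment vs. Col-0 WT with drought treatment	Plant defense related mutant	1713	244	23	0.884965	0.182514
Pseudomonas syringae pv phaseolicola infiltration for 6 hr	Pathogen infection	1090	161	21	0.899435	0.177085
upf1 mutant vs WT	Others	268	85	26	0.82047	0.176332
WT (Col-0) Bgh infection vs. WT control	Pathogen infection	2489	296	20	0.924127	0.176158
6 hr control vs 0 hr control	Others	1128	154	20	0.924756	0.174548
shoot under potassium starvation	Others	1293	168	20	0.929743	0.173504
Pst DC3118 Coronatine infection 24 hr	Pathogen infection	483	82	18	0.955476	0.173289
ataf1-1 mutant, Bgh infection vs. ataf1-1 mutant control	Pathogen infection	3165	346	19	0.938368	0.171836
Phytophthora infection for 6 hr	Pathogen infection	1920	237	20	0.912724	0.171609
S15-118 mutant vs. WT	Others	160	63	23	0.854106	0.169901
Leaf, eds16 mutant, Golovinomyces orontii infection for 5 d vs. eds16 mutant, 0 d control	Pathogen infection	152	54	20	0.905124	0.166002
35S::ERF104, Flg22 treatment vs. 35S::ERF104, control	Plant defense elicitor	1388	160	18	0.95289	0.164251
pmr5 mutant vs. WT	Plant defense related mutant	93	43	18	0.947634	0.16293
E. coli 0157:H7 infection 7 hr	Pathogen infection	582	88	18	0.940332	0.161603
SA effects at 4 hr (Kin-0)	Plant defense elicitor	237	59	19	0.919729	0.161515
S58-2 mutant vs. WT	Others	175	56	20	0.892642	0.160508
Leaf, eds16, Golovinomyces orontii infection for 7 d vs. WT, infection for 7 d	Plant defense related mutant	455	108	25	-0.78266	0.158267
Rosette leaf, flu mutant vs. WT	Others	1024	138	19	0.89576	0.157622
Triazolopyrimidine herbicide treatment vs. control	Herbicide	1768	191	17	0.938601	0.156599
Col-0 WT, Pst DC3000 (avrRpt2) infection vs. uninoculated control	Pathogen infection	629	110	21	0.827156	0.149031
cpr5npr1svi1 triple mutant	Plant defense related mutant	388	89	23	0.799919	0.14811
DC3000hrpA vs WT at 14 hr pathogen treatment	Pathogen infection	891	107	16	0.93812	0.148062
2 hr control vs 0 hr control	Others	864	113	18	0.898938	0.146689
OGs effects for 1 hr	Plant defense elicitor	866	122	19	0.86349	0.145894
AgNO3	Others	807	117	19	0.854076	0.143679
Rosette leaf, flu mutant, over-expressing tAPX vs. WT, over-expressing tAPX	Others	1414	149	16	0.926977	0.142656
Elicitor experiment, HrpZ treatment for 2 hr vs. 2 hr control	Plant defense elicitor	2043	211	17	0.905002	0.142587
Imidazolinone herbicide treatment vs. control	Herbicide	1843	176	15	0.948063	0.14226
flg22 effects for 1 hr	Plant defense elicitor	1714	180	17	0.908522	0.141837
Pseudomonas syringae pv phaseolicola infiltration for 2 hr	Pathogen infection	319	65	18	0.869464	0.140394
Pst DC3000 infection (5 hr) in wrky17 mutant	Pathogen infection	2918	271	16	0.918935	0.138735
Elicitor experiment, GST-NPP1 treatment for 4 hr vs. 4 hr control	Others	2044	214	17	0.882373	0.137416
high nitrogen effects	Others	1155	131	17	-0.89249	0.135869
Pst DC3000 infection (5 hr) in WT	Pathogen infection	2782	264	16	0.901735	0.135735
Whole plant, mkk1/mkk2 vs. WT	Plant defense related mutant	2559	241	16	0.905859	0.134531
Whole plant, mkk2, 24 h BTH treatment vs. WT, 24 h BTH treatment	Plant defense elicitor	262	55	17	0.886747	0.134518
Whole plant, mkk1/mkk2, 24 h BTH vs. WT 24 h BTH	Plant defense elicitor	1887	197	17	0.879539	0.134389
gh3.5-1D mutant Pst DC3000(avrRpt2) vs. gh3.5-1D un-inoculated control	Pathogen infection	2533	248	17	0.888302	0.134312
Elicitor experiment, Flg-22 treatment for 4 hr vs. 4 hr control	Plant defense elicitor	1259	134	16	0.906282	0.13422
senescence effects in pod	Senescence	1722	195	18	0.850641	0.134189
sni1 mutant	Plant defense related mutant	170	72	26	0.713915	0.1332
Pst DC3000 infection (5 hr) in wrky11 mutant	Pathogen infection	3067	276	16	0.909859	0.132532
Primisulfuron herbicide treatment vs. control	Herbicide	2805	242	15	0.931266	0.131749
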