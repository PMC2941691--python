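tc_name	treatment_type	fold_change	p_value
Seedling, SA treatment vs. control	Plant defense elicitor	338.61	0.0024
Csn5 (csn5a-2 csn5b) mutant, light vs. wild type, light	Plant defense related mutant	230.14	3.83E-05
gh3.5-1D mutant Pst DC3000(avrRpt2) vs. gh3.5-1D un-inoculated control	Pathogen infection	220.44	2.07E-06
Leaf, eds16 mutant, Golovinomyces orontii infection for 7 d vs. eds16 mutant, 0 d control	Pathogen infection	160.28	2.21E-05
Csn4-1 mutant, light vs. wild type, light	Plant defense related mutant	130.35	6.81E-04
Csn4-1 mutant vs. wild type	Plant defense related mutant	125.67	0.0011
BTH Effect for 24 hr in wrky18 mutant	Plant defense elicitor	111.62	0.0012
Whole plant, mkk1/mkk2 vs. WT	Plant defense elicitor	108.59	5.48E-04
senescence effects in pod	Senescence	97.64	2.67E-05
cpr5scv1 double mutant	Plant defense related mutant	88.61	0.0385
Pst DC3000 infection (12 hr) in WT	Pathogen infection	83.37	0.0181
BTH Effect for 24 hr in WT	Plant defense elicitor	77.47	0.012
Whole plant, WT, 24 h BTH vs. WT control	Plant defense elicitor	71.71	3.44E-07
Csn3-1 mutant, light vs. wild type, light	Plant defense related mutant	67.19	7.58E-05
120 hr Erysiphe orontii infection	Pathogen infection	64.8	0.0053
Whole plant, mkk2, 24 h BTH vs. mkk2 control	Plant defense elicitor	63.45	0.0042
Col-0 WT, Pst DC3000 (avrRpt2) infection vs. un-inoculated control	Pathogen infection	60.32	0.0182
Cold 7 days effects	Others	58.93	0.0061
cpr5 mutant	Plant defense related mutant	56.63	0.0354
Pst DC3000 infection (12 hr) in wrky17 mutant	Pathogen infection	55.62	0.0293
siz1-3 mutant drought with treatment vs. Col-0 WT with drought treatment	Plant defense related mutant	52.98	0.0034
Brm-101 mutant vs. Ler WT	Others	52.5	0.0221
96 hr Erysiphe orontii infection	Pathogen infection	49.32	2.50E-05
Phytophthora infection for 24 hr	Pathogen infection	47.65	3.19E-05
32 hr PsES4326 infection vs 9 hr PsES4326 infection	Pathogen infection	41.11	0.0267
siz1-3 mutant vs. Col-0 WT	Plant defense related mutant	38.88	0.0031
Pst DC3000 infection (12 hr) in wrky11 mutant	Pathogen infection	37.07	0.0093
24 hr PsES4326 infection vs 9 hr PsES4326 infection	Pathogen infection	33.64	0.0297
E2Fa-DPa over-expressing	Others	32.75	0.009
Cotyledon	Others	30.2	8.69E-05
Chitin receptor mutant, chitooctaose treatment vs. Wild type, chitooctaose treatment	Plant defense elicitor	29.64	7.04E-04
shoot vs root	Others	29.61	8.02E-04
Csn5 (csn5a-2 csn5b) mutant, dark vs. wild type, dark	Plant defense related mutant	29.26	0.007
Chitin receptor mutant vs. Wild type	Plant defense related mutant	28.92	3.09E-05
flower stage 15, sepals	Others	28.05	1.08E-04
Whole plant, mkk1, 24 h BTH vs. mkk1 control	Plant defense elicitor	26.74	0.0174
Leaf, WT, Golovinomyces orontii infection for 7 d vs. 0 d control	Pathogen infection	26.06	2.36E-07
BTH Effect for 8 hr in WT	Plant defense elicitor	26.06	0.0201
BTH Effect for 8 hr in wrky18 mutant	Plant defense elicitor	25.92	3.30E-04
camta3-2 mutant vs. wild type	Plant defense related mutant	22.87	0.0358
cdpk6-yfp 4 transgene effects	Others	20.98	0.0151
PsmES4326 infection for 32 hr	Pathogen infection	19.53	0.0079
Leaf, WT, Golovinomyces orontii infection for 5 d vs. 0 d control	Pathogen infection	17.73	2.80E-06
S15-118 mutant vs. WT	Others	17.6	0.0368
PsmES4326 infection for 24 hr	Pathogen infection	16.37	0.0072
flower stage 15	Others	14.82	1.09E-04
BTH treatment in WT vs. WT control	Plant defense elicitor	14.78	3.70E-04
Pseudomonas syringae pv phaseolicola infiltration for 24 hr	Pathogen infection	12.87	0.0015
mature leaves, 35 days after sowing vs. Average	Others	12.58	0.0232
72 hr Erysiphe orontii infection	Pathogen infection	12.55	0.0086
old rosette leaf vs young rosettet leaf in WT	Senescence	10.82	0.0235
SPH1 knockout vs WT in young rosette leaf	Others	10.69	0.0187
pmr5 pmr6 double mutant vs. WT	Plant defense related mutant	10.46	0.0293
Pseudomonas syringae pv tomato avrRpm1 infiltration for 24 hr	Pathogen infection	10.19	0.0036
flower stage 12 equivalent (7)	Others	8.83	3.61E-04
sni1 mutant	Others	8.59	0.0117
flower stage 12 equivalent (6)	Others	8.58	2.48E-04
High nitrogen and glucose effects	Others	7.64	0.0015
Pnp1-1, phosphate deficiency 1 wk vs. WT, phostphate deficiency 1 wk	Others	6.92	0.0259
Pseudomonas syringae pv tomato DC3000 hrcC-infiltration for 24 hr	Pathogen infection	6.78	1.75E-04
glucose effects	Others	6.42	7.38E-04
Pnp1-1, phosphate efficiency 1 wk vs. WT, phostphate efficiency 1 wk	Others	6.36	0.0173
mil4 overexpression line with BTH treatment vs. mil4 overexpression line control	Plant defense elicitor	6.3	5.77E-04
flower stage 12, sepals	Others	6.2	3.95E-04
arr10 arr12 double null mutant effects under cytokinin	Others	6.03	0.0034
pmr5 mutant vs. WT	Plant defense related mutant	5.88	0.0412
WT, INA 48 h vs. control 48 h	Others	5.77	0.0437
pnp1-1 mutant, phosphate starvation for 1 wk vs. pnp1-1 mutant, 1 wk control	Others	5.74	0.0402
BTH treatment in mil4 mutant vs. H2O in mil4 mutant	Plant defense elicitor	5.52	0.0028
Cotyledon	Others	5.46	3.86E-04
WT, phosphate starvation for 1 wk vs. 1 wk control	Others	5.28	0.0166
seedling 3 vs average	Others	5.1	8.30E-04
seedling 2 vs average	Others	4.87	0.001
SAM SE, 35S:AGL15 vs. WT	Others	4.64	0.0461
16 hr Pseudomonas infection	Pathogen infection	4.58	0.0114
gl1T rosette leaf #4, 1 cm long	Others	4.53	1.56E-04
Pseudomonas syringae pv phaseolicola infiltration for 6 hr	Pathogen infection	4.33	0.0308
senescing leaves	Senescence	4.32	3.95E-05
Botrytis cinerea infection on 48 hpi leaf	Pathogen infection	4.17	0.0247
Col-0 rosette leaf #4	Others	4.08	0.0016
mil4 mutant vs. WT	Plant defense related mutant	3.81	0.0031
gl1T rosette leaf #12	Others	3.64	3.24E-04
flower stage 12 equivalent (5)	Others	3.62	0.0028
Leaf	Others	3.22	0.0016
cauline leaves	Others	3.13	0.0023
shoot under potassium starvation	Others	3	0.0098
Met1-3 mutant leaf (4th generation) vs. Col-0 WT	Others	2.9	0.0353
shoot under Caesium treatment	Others	2.9	0.0061
Col-0 rosette leaf #4	Others	2.76	0.0018
24 hr control vs 0 hr control	Others	2.7	0.0158
Ambient CO2 and Ambient Light at 96 hr vs 0 hr	Others	2.49	0.0364
rosette leaf # 2	Others	2.45	0.0075
leaf 7, distal half	Others	2.42	0.0023
HSP90 reduced mutant (RNAi-B1) vs. Control-3	Others	2.05	0.0063
gh3.5-1D mutant, Pst DC3000 (avrRpt2) infection vs. Col-0 WT, Pst DC3000 (avrRpt2) infection	Others	2.03	0.0263
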