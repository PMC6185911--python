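species	n_replicates	habitat_class	mean_richness	mean_richness_sd	core_size	core_fraction_pct	core_fraction_sd	n_species_specific	species_specific_pct_of_core	n_sw_shared	sw_shared_pct_of_core
Aaptos suberitoides	13	HMA	740	139	134	77.6	6.2	6	1.1	53	48.79
Neofibularia hartmani	10	HMA	883	182	167	94.2	1.6	32	4.4	67	71.59
Suberea cf. laboutei	3	HMA	812	133	206	79.2	7.8	65	20.6	61	26.67
Amphimedon paraviridis	10	LMA	587	223	57	61.9	22.1	1	0.0	52	99.54
Antho sp.	3	LMA	1587	872	404	88.2	5.1	71	2.0	107	9.90
Callyspongia sp.	2	LMA	850	507	229	83.9	2.3	0	1.0	76	38.55
Clathria reinwardti	15	LMA	769.1	171	54	88.4	7.3	0	0.0	36	90.40
Clathria sp.	4	LMA	838	420	144	69.6	19.9	2	0.3	50	33.57
Dendroxea sp.	2	LMA	795	118	310	77.7	13.9	50	11.6	99	33.99
Dysidea sp.	3	LMA	1811	902	453	84.6	6.8	66	3.7	131	27.35
Gellioides cf. gracilis	9	LMA	647	123	138	82.9	5.3	1	0.4	69	53.03
Gellioides sp.	4	LMA	456	87	96	49.3	27.5	8	25.7	83	93.22
Haliclona sp.	3	LMA	1343	611	365	79.5	9.7	44	3.1	123	16.06
Haliclona (Gellius) toxotes	3	LMA	892	327	249	74.3	4.2	15	0.2	88	60.34
Monanchora unguiculata	3	LMA	622	115	254	86.0	7.8	12	0.3	93	58.71
Mycale sp.	4	LMA	1720	1576	80	54.0	7.3	2	0.7	42	77.51
Phorbas sp.	3	LMA	905	349	214	86.6	6.6	14	0.6	77	52.20
Pseudosuberites sp.	2	LMA	1791	1205	579	86.4	9.4	17	14.3	125	10.97
Thrinacophora rhaphidophora	2	LMA	1392	231	600	89.1	5.2	195	9.6	169	22.67
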