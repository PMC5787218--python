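case	gene_id	gene_product	location	AA	BB_searsii	BB_speltoides	DD	AABB	AABBDD
1	TRIAE_CS42_1DL_TGACv1_061151_AA0187150	DnaJ homolog subfamily C member 13	Intron	1	1	1	1	1	1
2	TRIAE_CS42_2BL_TGACv1_129350_AA0379730	CLPTM1-like membrane protein cnrB	Intron	1	1	1	1	1	1
3	TRIAE_CS42_7BL_TGACv1_577050_AA1863990	Predicted protein	Exon	1	1	1	1	1	1
4	TRIAE_CS42_7BS_TGACv1_591977_AA1927210	Predicted protein	100 bp downstream	1	1	1	1	1	1
5	TRIAE_CS42_4DS_TGACv1_363130_AA1183390	Rht-D1b	Intron	1	1	1	1	1	1
6	TRIAE_CS42_4DL_TGACv1_342699_AA1119920	Superoxide dismutase [Cu-Zn] 3	Intron	1	1	1	1	1	1
7	TRIAE_CS42_U_TGACv1_640941_AA2079970	Disease resistance protein RPP13-like	Exon	0	0	0	0	0	1
8	TRIAE_CS42_1BS_TGACv1_050314_AA0170550	Putative Serine/threonine-protein kinase CBK1	Intron	0	0	0	0	0	1
9	TRIAE_CS42_7BL_TGACv1_577920_AA1886220	Zinc transporter ten-like	Intron	0	0	0	0	1	1
10	TRIAE_CS42_1BL_TGACv1_032021_AA0124300	Putative E3 ubiquitin-protein ligase HERC1	Intron	0	0	0	0	1	1
11	TRIAE_CS42_1BS_TGACv1_049809_AA0161910	Predicted protein	Intron	0	0	0	0	1	1
12	TRIAE_CS42_6BL_TGACv1_499645_AA1588080	Rho guanine nucleotide exchange factor 8	Intron	0	0	0	0	1	1
13	TRIAE_CS42_5AL_TGACv1_377324_AA1245930	Putative ATP-dependent RNA helicase DHX36	Intron	0	0	0	0	1	1
14	TRIAE_CS42_5BL_TGACv1_406235_AA1342580	Predicted protein	Intron	0	0	0	0	1	1
15	TRIAE_CS42_2AL_TGACv1_093126_AA0272720	Cell division protein FtsZ homolog 1, chloroplastic	Intron	0	0	0	0	1	1
16	TRIAE_CS42_2BL_TGACv1_130367_AA0409600	Exocyst complex component 2	Intron	0	0	0	0	1	1
17	TRIAE_CS42_3B_TGACv1_220590_AA0709880	Josephin family protein	Intron	0	0	0	0	1	1
18	TRIAE_CS42_1BS_TGACv1_049553_AA0156720	Predicted protein	Exon/Intron	0	0	0	0	1	1
19	TRIAE_CS42_2BS_TGACv1_146572_AA0468420	2-dehydro-3-deoxyphosphooctonate aldolase	Intron	0	0	0	0	1	1
20	TRIAE_CS42_2AL_TGACv1_096183_AA0317680	ATP-dependent RNA helicase SUPV3L1, mitochondrial	Intron	0	0	0	0	1	1
21	TRIAE_CS42_2BL_TGACv1_129880_AA0398630	Oligoribonuclease	Intron	0	0	0	0	1	1
22	TRIAE_CS42_1AL_TGACv1_000103_AA0003430	Predicted protein	Intron	0	0	0	0	1	1
23	TRIAE_CS42_5BL_TGACv1_405351_AA1325650	MADS-box transcription factor 14	Intron	0	0	0	0	1	1
24	TRIAE_CS42_5BL_TGACv1_404700_AA1308770	E3 ubiquitin-protein ligase AIP2	Intron	0	0	0	0	1	NA
25	TRIAE_CS42_2DL_TGACv1_158055_AA0507480	Chloride channel protein CLC-c	Intron	0	0	0	1	0	1
26	TRIAE_CS42_2DS_TGACv1_177403_AA0575920	5'-3' exoribonuclease 3	Intron	0	0	0	1	0	1
27	TRIAE_CS42_4DS_TGACv1_361106_AA1161070	Inositol hexakisphosphate and diphosphoinositol-pentakisphosphate kinase 1	Intron	0	0	0	1	0	1
28	TRIAE_CS42_4DL_TGACv1_343519_AA1135850	Conserved oligomeric Golgi complex subunit 6-like	Intron	0	0	0	1	0	1
29	TRIAE_CS42_6DL_TGACv1_526989_AA1696800	Serine/threonine-protein kinase	Intron	0	0	0	1	0	1
30	TRIAE_CS42_4AL_TGACv1_290382_AA0984800	ERBB-3 BINDING PROTEIN 1	Intron	1	0	0	0	1	1
31	TRIAE_CS42_5AL_TGACv1_378959_AA1255190	Leucine zipper protein	Intron	1	0	0	0	1	1
32	TRIAE_CS42_2AL_TGACv1_093836_AA0287830	Putative pectinesterase/pectinesterase inhibitor 51	Intron	1	0	0	0	1	1
33	TRIAE_CS42_3AS_TGACv1_211370_AA0689310	C3H2C3 RING-finger protein	Exon/Intron	1	0	0	0	1	NA
34	TRIAE_CS42_7AL_TGACv1_558277_AA1791890	ELAV-like protein 1	Intron	0	1	1	0	1	1
35	TRIAE_CS42_2BS_TGACv1_145935_AA0449980	Mediator of RNA polymerase II transcription subunit 14-like	Intron	0	0	1	0	1	1
36	TRIAE_CS42_5BL_TGACv1_407697_AA1358910	Calcineurin-like metallo-phosphoesterase superfamily protein	Intron	0	0	1	0	1	1
37	TRIAE_CS42_4AL_TGACv1_288293_AA0943850	Rho GTPase-activating protein 7	Intron	1	1	0	1	1	1
38	TRIAE_CS42_7DS_TGACv1_624740_AA2063030	Kanadaptin	Intron	1	0	1	1	1	1
39	TRIAE_CS42_4DL_TGACv1_342534_AA1116030	Serine-aspartate repeat-containing protein I-like	Intron	0	1	1	1	1	1
40	TRIAE_CS42_1BS_TGACv1_049347_AA0149810	SIN3 transcription regulator family member B	Intron	1	0	1	1	1	1
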