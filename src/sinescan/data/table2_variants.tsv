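gene_id	gene_product	location	n_variants	n_with_element
TRIAE_CS42_1AL_TGACv1_002495_AA0042400	Putative methyltransferase PMT7	1A	5	3
TRIAE_CS42_1AS_TGACv1_020149_AA0075200	Protein STIP1-like protein / Ankyrin	1A	3	3
TRIAE_CS42_1BL_TGACv1_030243_AA0083440	3-deoxy-manno-octulosonate cytidylyltransferase, mitochondrial	1B	3	2
TRIAE_CS42_1BS_TGACv1_051223_AA0178630	Methyl-CpG-binding domain protein 4	1B	9	3
TRIAE_CS42_2AL_TGACv1_094480_AA0298520	Heterogeneous nuclear ribonucleoprotein Q	2A	6	1
TRIAE_CS42_2AL_TGACv1_095668_AA0313540	Cysteine proteinases superfamily protein	2A	3	1
TRIAE_CS42_2BL_TGACv1_130920_AA0419930	Serine/threonine-protein kinase	2B	3	1
TRIAE_CS42_2BL_TGACv1_131783_AA0432150	AMP-activated protein kinase, gamma regulatory subunit	2B	2	1
TRIAE_CS42_2BL_TGACv1_131823_AA0432620	SNARE associated Golgi protein family	2B	6	3
TRIAE_CS42_2BS_TGACv1_148673_AA0494490	Predicted membrane protein	2B	2	1
TRIAE_CS42_2DS_TGACv1_177434_AA0577040	Predicted protein	2D	3	1
TRIAE_CS42_3AL_TGACv1_193715_AA0618280	4-coumarate-CoA ligase-like 9	3A	8	1
TRIAE_CS42_3AL_TGACv1_194196_AA0628350	Predicted protein	3A	2	2
TRIAE_CS42_3AS_TGACv1_211514_AA0690950	Retinol dehydrogenase 14	3A	3	1
TRIAE_CS42_3B_TGACv1_222217_AA0760010	Potassium transporter 5	3B	2	2
TRIAE_CS42_3B_TGACv1_224095_AA0792250	Vacuolar-processing enzyme	3B	6	3
TRIAE_CS42_3B_TGACv1_227320_AA0822830	Zinc finger CCCH domain-containing protein 12	3B	4	1
TRIAE_CS42_4AL_TGACv1_288915_AA0961300	Protein kinase superfamily protein	4A	3	2
TRIAE_CS42_4AL_TGACv1_291111_AA0992310	Noncoding RNA	4A	2	1
TRIAE_CS42_4AS_TGACv1_306183_AA1003850	Periplasmic serine endoprotease DegP-like	4A	2	2
TRIAE_CS42_4BL_TGACv1_321946_AA1067110	Predicted protein	4B	3	2
TRIAE_CS42_4BS_TGACv1_328309_AA1086060	Protein CDC73 homolog	4B	3	1
TRIAE_CS42_4BS_TGACv1_328640_AA1091470	Predicted protein	4B	4	2
TRIAE_CS42_4DL_TGACv1_343838_AA1140270	FAR-RED IMPAIRED RESPONSE 1-like	4D	2	2
TRIAE_CS42_5AL_TGACv1_374408_AA1199410	DExH-box ATP-dependent RNA helicase DExH16, mitochondrial	5A	3	1
TRIAE_CS42_5AL_TGACv1_374413_AA1199550	Disease resistance RPP8-like protein 3	5A	2	2
TRIAE_CS42_5AL_TGACv1_375575_AA1223920	Non-coding RNA	5A	2	1
TRIAE_CS42_5BL_TGACv1_404363_AA1296950	Predicted protein	5B	3	2
TRIAE_CS42_5BL_TGACv1_406039_AA1339580	Carbamoyl-phosphate synthase small chain, chloroplastic	5B	4	2
TRIAE_CS42_5BL_TGACv1_407028_AA1352680	FBD-associated F-box protein	5B	2	2
TRIAE_CS42_5BL_TGACv1_407299_AA1355630	Signal recognition particle-related/SRP-related	5B	3	1
TRIAE_CS42_5BL_TGACv1_408403_AA1363260	Predicted protein	5B	9	1
TRIAE_CS42_5BS_TGACv1_424513_AA1390380	Putative WRKY transcription factor 3	5B	2	1
TRIAE_CS42_6AL_TGACv1_472758_AA1525700	U-box domain-containing protein 11	6A	3	1
TRIAE_CS42_6AS_TGACv1_485705_AA1550580	Predicted protein	6A	3	3
TRIAE_CS42_6BL_TGACv1_499355_AA1579140	Lysyl-tRNA synthetase	6B	4	2
TRIAE_CS42_6BL_TGACv1_501000_AA1612460	F-box/FBD/LRR-repeat protein	6B	4	1
TRIAE_CS42_6BS_TGACv1_514524_AA1660940	Predicted protein	6B	6	1
TRIAE_CS42_6BS_TGACv1_514925_AA1665920	Transcription termination factor MTERF8, chloroplastic-like	6B	2	2
TRIAE_CS42_7AL_TGACv1_557374_AA1780510	Polyadenylate-binding protein RBP45-like	7A	4	3
TRIAE_CS42_7AS_TGACv1_569582_AA1819670	Predicted protein	7A	3	1
TRIAE_CS42_7BL_TGACv1_577086_AA1865600	ELAV-like protein 1	7B	2	1
TRIAE_CS42_7BL_TGACv1_577812_AA1883950	Hydroxyproline O-galactosyltransferase HPGT1	7B	2	1
TRIAE_CS42_7BS_TGACv1_591848_AA1923570	Transcription initiation factor TFIID subunit 10	7B	3	1
TRIAE_CS42_7BS_TGACv1_593481_AA1951940	Putative clathrin assembly protein	7B	3	1
TRIAE_CS42_U_TGACv1_640735_AA2071780	Putative rust resistance kinase Lr10	NA	2	2
TRIAE_CS42_U_TGACv1_640941_AA2079970	Disease resistance protein RPP13-like	NA	2	2
TRIAE_CS42_U_TGACv1_641735_AA2102860	Methionine S-methyltransferase	NA	2	2
TRIAE_CS42_U_TGACv1_641821_AA2105030	Putative Exocyst complex component 7	NA	2	1
TRIAE_CS42_U_TGACv1_643249_AA2129660	Mitochondrial inner membrane translocase complex, subunit Tim44-related protein	NA	2	1
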