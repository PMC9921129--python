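compound	name	column_id	rt_min	ri_cal	ri_lit	enantiomer_group	elution_rank	is_internal_standard	range_low_mg_ml	range_high_mg_ml
alpha_pinene	(+)-alpha-pinene	chiral_cd	9.58	927				0	0.0062	0.6202
camphene	camphene (isomer 1)	chiral_cd	9.77	931		camphene	1	0	0.0028	0.0566
camphene	camphene (isomer 2)	chiral_cd	10.27	942		camphene	2	0	0.0028	0.0566
beta_pinene	(-)-beta-pinene	chiral_cd	11.49	967				0	0.0028	0.0561
cis_3_hexen_1_ol	cis-3-hexen-1-ol	chiral_cd	15.21					1	0.0033	0.1320
alpha_terpinene	alpha-terpinene	chiral_cd	16.26	1057				0	0.0031	0.0618
limonene	limonene	chiral_cd	17.06	1071				0	0.0031	0.0619
p_cymene	p-cymene	chiral_cd	17.16	1073				0	0.0028	0.0555
rose_oxide	(+)-rose oxide	chiral_cd	20.28	1126		rose_oxide	1	0	0.0100	0.1994
rose_oxide	(-)-rose oxide	chiral_cd	20.43	1129		rose_oxide	2	0	0.0100	0.1994
linalool	linalool (isomer 1)	chiral_cd	23.18	1175		linalool	1	0	0.0033	0.1658
linalool	linalool (isomer 2)	chiral_cd	23.87	1186		linalool	2	0	0.0033	0.1658
phenylethanol	phenylethanol	chiral_cd	29.82	1286				0	0.0024	0.1219
citral	citral (isomer 1)	chiral_cd	30.66	1300		citral	1	0	0.0032	0.0644
citronellol	citronellol (isomer 1)	chiral_cd	31.95	1321		citronellol	1	0	0.0099	0.9939
citronellol	citronellol (isomer 2)	chiral_cd	32.06	1323		citronellol	2	0	0.0099	0.9939
nerol	nerol	chiral_cd	32.35	1328				0	0.0051	0.5071
citral	citral (isomer 2)	chiral_cd	33.26	1344		citral	2	0	0.0032	0.0644
geraniol	geraniol	chiral_cd	34.30	1361				0	0.0101	1.0055
citronellyl_acetate	citronellyl acetate (isomer 1)	chiral_cd	35.16	1376		citronellyl_acetate	1	0	0.0081	0.0542
citronellyl_acetate	citronellyl acetate (isomer 2)	chiral_cd	35.27	1378		citronellyl_acetate	2	0	0.0081	0.0542
neryl_acetate	neryl acetate	chiral_cd	35.87	1388				0	0.0022	0.1097
beta_damascenone	beta-damascenone (isomer 1)	chiral_cd	36.70	1402		beta_damascenone	1	0	0.0507	1.0143
geranyl_acetate	geranyl acetate	chiral_cd	37.78	1421				0	0.0063	0.1266
beta_caryophyllene	beta-caryophyllene	chiral_cd	37.87	1423				0	0.0033	0.0666
beta_damascenone	beta-damascenone (isomer 2)	chiral_cd	38.11	1427		beta_damascenone	2	0	0.0507	1.0143
beta_damascone	beta-damascone	chiral_cd	38.64	1436				0	0.0013	0.0660
eugenol	eugenol	chiral_cd	39.61	1453				0	0.0025	0.1228
methyleugenol	methyleugenol	chiral_cd	41.11	1479				0	0.0023	0.1153
farnesol	farnesol	chiral_cd	58.67	1802				0	0.0061	0.1227
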