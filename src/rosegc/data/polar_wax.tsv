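compound	name	column_id	rt_min	ri_cal	ri_lit	enantiomer_group	elution_rank	is_internal_standard	range_low_mg_ml	range_high_mg_ml
alpha_pinene	alpha-pinene	polar_wax	4.24	1013	1013			0	0.0062	0.6202
camphene	camphene	polar_wax	5.37	1048	1053			0	0.0011	0.0545
beta_pinene	beta-pinene	polar_wax	6.84	1096	1096			0	0.0006	0.0561
alpha_terpinene	alpha-terpinene	polar_wax	10.95	1159	1159			0	0.0012	0.0618
limonene	limonene	polar_wax	12.38	1166	1176			0	0.0012	0.0619
p_cymene	p-cymene	polar_wax	18.26	1264	1268			0	0.0011	0.0555
rose_oxide	rose oxide	polar_wax	22.51	1344	1339			0	0.0020	0.2004
cis_3_hexen_1_ol	cis-3-hexen-1-ol	polar_wax	24.04					1	0.0033	0.1320
linalool	linalool	polar_wax	28.98	1383	1380			0	0.0013	0.0533
beta_caryophyllene	beta-caryophyllene	polar_wax	29.79	1550	1548			0	0.0203	1.0143
beta_damascenone	beta-damascenone	polar_wax	31.16	1582	1586			0	0.0027	0.0542
citronellyl_acetate	citronellyl acetate	polar_wax	31.68	1636	1803			0	0.0013	0.0644
citral	citral	polar_wax	32.00	1659	1658			0	0.0022	0.0874
neryl_acetate	neryl acetate	polar_wax	33.15	1671	1678			0	0.0063	0.1013
geranyl_acetate	geranyl acetate	polar_wax	33.84	1722	1719			0	0.0099	0.7951
citronellol	citronellol	polar_wax	34.16	1754	1746			0	0.0050	0.4038
nerol	nerol	polar_wax	34.86	1768	1755			0	0.0012	0.0970
phenylethanol	phenylethanol	polar_wax	35.03	1800	1798			0	0.0100	0.8006
geraniol	geraniol	polar_wax	35.88	1806	1875			0	0.0023	0.0918
methyleugenol	methyleugenol	polar_wax	39.09	1848	1841			0	0.0025	0.1228
eugenol	eugenol	polar_wax	41.91	2008	2001			0	0.0025	0.1272
farnesol	farnesol	polar_wax	45.37	2161	2167			0	0.0062	0.6202
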