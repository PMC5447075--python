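group_id	members	name	e1_ld_s	e1_ld_mb	e1_ld_tl	e2_ld_s	e2_ld_mb	e2_ld_tl	e3_ld_s	e3_ld_mb	e3_ld_tl	e3_ld_pg
AT2G33380	AT2G33380	Caleosin-related family protein (CLO3/RD20)	208.0	30.5	202.7	61.7	21.6	53.7	107.1	36.7	102.1	64.0
AT3G01420	AT3G01420	Peroxidase superfamily protein (alpha-DOX1)	2.8	40.2	3.1	19.8	21.5	21.7	3.2	3.3	6.6	4.4
AT1G67360	AT1G67360	Rubber elongation factor protein (SRPP1/LDAP1)	114.3	67.1	80.1	26.4	22.0	34.3	66.0	57.8	69.6	83.9
AT1G74010	AT1G74010;AT1G74020	Strictosidine synthase 2 (STR2)	126.4	14.8	79.2	45.7	5.8	22.4	86.3	4.3	19.8	18.4
AT5G63910	AT5G63910	Farnesylcysteine lyase (FCLY)	20.9	7.6	11.9	11.3	9.6	18.3	98.8	3.8	14.9	53.0
AT2G25450	AT2G25450	2OG and Fe(II)-dependent oxygenase superfamily protein (GSL-OH)	43.2	8.7	51.1	83.7	4.0	54.0	nd	nd	nd	nd
AT5G48180	AT5G48180	Nitrile specifier protein 5 (NSP5)	3.4	125.6	42.2	2.3	2.0	13.3	nd	nd	nd	nd
AT3G03470	AT3G03470	Cytochrome P450 family 87 subfamily A	9.0	7.4	28.7	15.5	2.6	7.5	nd	nd	nd	nd
AT1G19670	AT1G19670	Chlorophyllase 1	2.2	6.9	16.8	3.8	11.5	31.6	247.8	1.2	7.9	65.9
AT2G36880	AT2G36880	Methionine adenosyltransferase 3 (SAMS3)	9.2	3.6	11.1	21.6	5.3	9.9	4.9	2.8	6.9	30.8
AT1G22410	AT1G22410;AT4G33510	3-Deoxy-d-arabino-heptulosonate 7-phosphate synthase (DHAP)	162.5	51.2	15.3	24.2	8.1	16.2	17.4	6.9	3.9	50.1
AT2G17840	AT2G17840	Early-responsive to dehydration 7 (ERD7)	10.2	13.8	10.2	12.3	5.7	8.6	3.7	1.1	0.7	15.4
AT5G64110	AT5G64110	Peroxidase superfamily protein	67.7	17.0	176.9	nd	nd	nd	53.7	6.8	41.1	15.4
AT5G09440	AT5G09440	EXORDIUM like 4	nd	nd	nd	4.0	20.9	10.6	4.7	7.2	10.5	30.2
AT2G06850	AT2G06850;AT3G23730;AT4G14130;AT5G13870	Xyloglucan endotransglucosylase/hydrolase group	nd	nd	nd	2.4	6.8	10.4	6.1	14.4	8.1	33.2
AT1G09850	AT1G09850	Xylem bark cysteine peptidase 3	79.4	17.9	26.9	nd	nd	nd	12.3	1.7	6.7	35.3
AT4G16190	AT4G16190	Papain family cysteine protease	120.4	32.1	15.8	nd	nd	nd	61.8	4.7	11.2	111.0
AT1G49240	AT1G49240;AT3G18780	Actin 8 / Actin 2	78.1	8.7	19.3	17.3	2.1	5.8	14.7	1.7	10.0	119.0
AT5G12250	AT5G12250	Beta-6 tubulin	15.6	4.4	15.5	nd	nd	nd	17.0	1.7	15.3	23.0
AT1G20010	AT1G20010;AT1G75780	Tubulin beta-5 / beta-1 chain	15.3	5.1	11.7	29.2	2.5	6.4	nd	nd	nd	nd
AT3G20320	AT3G20320	Trigalactosyldiacylglycerol2 (TGD2)	21.7	6.7	6.8	22.9	7.0	11.9	13.3	1.5	10.7	27.3
AT1G19910	AT1G19910;AT1G75630;AT2G16510	ATPase F0/V0 complex subunit C group	27.1	2.3	5.6	64.4	9.2	29.4	22.7	3.9	9.2	66.4
AT2G41560	AT2G41560	Autoinhibited Ca2+-ATPase isoform 4 (ACA4)	57.5	3.5	9.2	22.1	1.6	7.9	0.5	0.2	0.7	28.1
AT3G56190	AT3G56190;AT3G56450	Alpha-soluble NSF attachment protein 2/1	12.0	1.5	8.3	10.3	2.6	6.5	3.8	0.8	2.2	12.8
AT4G04910	AT4G04910	N-ethylmaleimide sensitive factor (NSF)	27.1	2.3	5.6	64.4	9.2	29.4	22.7	3.9	9.2	66.4
AT4G19210	AT4G19210	ATP-Binding Cassette E2	20.5	1.8	11.4	9.9	5.0	9.1	nd	nd	nd	nd
AT5G16550	AT5G16550	Unknown protein (AtULP)	999.7	208.9	397.7	151.4	42.9	113.6	112.7	81.5	44.6	26.5
AT5G44020	AT5G44020	HAD superfamily subfamily IIIB acid phosphatase	155.2	7.8	121.1	9.7	7.5	36.9	nd	nd	nd	nd
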