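group_id	members	name	top3_exp1	top3_exp2	top3_exp3	published_average	published_mass_pct
AT2G33380	AT2G33380	Caleosin-related family protein (CLO3/RD20)	1.16E+08	2.35E+07	1.62E+07	5.20E+07	50.18
AT3G01420	AT3G01420	Peroxidase superfamily protein (alpha-DOX1)	5.50E+05	2.30E+05	4.47E+04	2.75E+05	0.28
AT1G67360	AT1G67360	Rubber elongation factor protein (SRPP1/LDAP1)	7.79E+07	7.87E+06	7.20E+06	3.10E+07	23.86
AT1G74010	AT1G74010;AT1G74020	Strictosidine synthase 2 (STR2)	5.18E+06	9.02E+05	6.55E+05	2.25E+06	2.06
AT5G63910	AT5G63910	Farnesylcysteine lyase (FCLY)	2.62E+05	2.83E+05	nd	2.05E+05	0.31
AT2G25450	AT2G25450	2OG and Fe(II)-dependent oxygenase superfamily protein (GSL-OH)	4.57E+05	2.06E+06	nd	1.26E+06	2.24
AT5G48180	AT5G48180	Nitrile specifier protein 5 (NSP5)	9.26E+04	1.98E+05	nd	1.45E+05	0.23
AT3G03470	AT3G03470	Cytochrome P450 family 87 subfamily A	7.30E+05	4.58E+05	nd	5.94E+05	0.62
AT1G19670	AT1G19670	Chlorophyllase 1	1.94E+06	1.15E+06	2.94E+05	1.13E+06	1.39
AT2G36880	AT2G36880	Methionine adenosyltransferase 3 (SAMS3)	1.97E+06	3.28E+05	2.05E+05	8.35E+05	0.72
AT1G22410	AT1G22410;AT4G33510	3-Deoxy-d-arabino-heptulosonate 7-phosphate synthase (DHAP)	1.47E+06	2.56E+05	5.09E+04	5.92E+05	0.43
AT2G17840	AT2G17840	Early-responsive to dehydration 7 (ERD7)	5.92E+05	3.32E+05	3.52E+04	3.20E+05	0.35
AT5G64110	AT5G64110	Peroxidase superfamily protein	4.31E+05	nd	5.16E+04	2.41E+05	0.17
AT5G09440	AT5G09440	EXORDIUM like 4	nd	2.85E+05	1.54E+05	2.20E+05	0.57
AT2G06850	AT2G06850;AT3G23730;AT4G14130;AT5G13870	Xyloglucan endotransglucosylase/hydrolase group	nd	9.88E+05	2.29E+05	6.08E+05	1.43
AT1G09850	AT1G09850	Xylem bark cysteine peptidase 3	1.51E+06	nd	7.19E+04	7.89E+05	0.42
AT4G16190	AT4G16190	Papain family cysteine protease	4.49E+05	nd	7.18E+04	2.60E+05	0.21
AT1G49240	AT1G49240;AT3G18780	Actin 8 / Actin 2	3.06E+07	6.72E+06	2.66E+06	1.33E+07	11.71
AT5G12250	AT5G12250	Beta-6 tubulin	1.52E+06	nd	1.23E+05	8.20E+05	0.51
AT1G20010	AT1G20010;AT1G75780	Tubulin beta-5 / beta-1 chain	5.17E+06	5.52E+05	2.00E+05	1.98E+06	1.28
AT3G20320	AT3G20320	Trigalactosyldiacylglycerol2 (TGD2)	6.67E+05	2.31E+05	4.06E+04	3.13E+05	0.29
AT1G19910	AT1G19910;AT1G75630;AT2G16510	ATPase F0/V0 complex subunit C group	2.12E+05	9.45E+04	1.90E+04	1.09E+05	0.12
AT2G41560	AT2G41560	Autoinhibited Ca2+-ATPase isoform 4 (ACA4)	3.32E+05	1.48E+05	7.60E+03	1.62E+05	0.15
AT3G56190	AT3G56190;AT3G56450	Alpha-soluble NSF attachment protein 2/1	9.64E+05	2.55E+05	6.13E+04	4.27E+05	0.37
AT4G04910	AT4G04910	N-ethylmaleimide sensitive factor (NSF)	2.12E+05	9.45E+04	1.90E+04	1.09E+05	0.12
AT4G19210	AT4G19210	ATP-Binding Cassette E2	3.26E+05	6.02E+04	nd	1.93E+05	0.13
AT5G16550	AT5G16550	Unknown protein (AtULP)	8.31E+06	6.93E+05	3.40E+05	3.12E+06	1.95
AT5G44020	AT5G44020	HAD superfamily subfamily IIIB acid phosphatase	nd	1.21E+05	nd	1.21E+05	0.25
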