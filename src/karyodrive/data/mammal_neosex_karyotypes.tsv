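order	family	genus	species	female_2n	male_2n	female_nf	male_nf	female_frac_acro	male_frac_acro	system	source
Primates	Aotidae	Aotus	azarae	50	49	74	76	0.52	0.45	X1X2Y	b59;b51
Primates	Aotidae	Aotus	boliviensis	50	49	64	63	0.72	0.71	X1X2Y	b42;b59
Primates	Aotidae	Aotus	inflatus	50	49	66	65	0.68	0.67	X1X2Y	b59
Primates	Aotidae	Aotus	sp.	50	49	74	73	0.52	0.51	X1X2Y	b50
Primates	Atelidae	Alouatta	belzebul	50	49	70	70	0.60	0.57	X1X2Y	b1
Primates	Atelidae	Alouatta	fusca	50	49	68	66	0.64	0.65	X1X2Y	b14;b13
Primates	Atelidae	Alouatta	palliata	54	53	78	76	0.56	0.57	X1X2Y	b43
Primates	Callitrichidae	Callimico	goeldii	48	47	72	71	0.50	0.49	X1X2Y	b45
Primates	Pitheciidae	Cacajao	calvus	46	45	62	62	0.65	0.62	X1X2Y	b21
Rodentia	Cricetidae	Deltamys	kempi	38	37	38	38	1.00	0.97	X1X2Y	b65;b49
Rodentia	Muridae	Mus	minutoides	36	35	36	36	1.00	0.97	X1X2Y	b47;b25
Rodentia	Muridae	Vandeleuria	oleracea	29	29	41	41	0.59	0.59	X1X2Y	b66
Chiroptera	Phyllostomidae	Choeroniscus	godmani	20	19	28	26	0.60	0.63	X1X2Y	b29;b58
Chiroptera	Phyllostomidae	Mesophylla	macconnelli	22	21	22	21	1.00	1.00	X1X2Y	b2
Artiodactyla	Bovidae	Tragelaphus	strepsiceros	32	31	58	58	0.19	0.13	X1X2Y	b75
Carnivora	Herpestidae	Herpestes	auropunctatus	36	35	56	54	0.44	0.46	X1X2Y	b23;b24
Pilosa	Megalonychidae	Choloepus	hoffmanni	49	49	58	58	0.82	0.82	X1X2Y	b11
Diprotodontia	Macropodidae	Lagorchestes	conspicillatus	16	15	16	15	1.00	1.00	X1X2Y	b46
Rodentia	Muridae	Mus	musculoides	18	19	36	35	0.00	0.16	XY1Y2	b73
Rodentia	Muridae	Taterillus	arenarius	30	31	36	36	0.80	0.84	XY1Y2	b17;b15
Rodentia	Muridae	Taterillus	petteri	18	19	28	28	0.44	0.53	XY1Y2	b17;b15
Rodentia	Muridae	Taterillus	pygargus	22	23	38	40	0.27	0.26	XY1Y2	b16
Rodentia	Muridae	Taterillus	sp.1	22	23	40	40	0.18	0.26	XY1Y2	b16
Rodentia	Muridae	Taterillus	sp.2	24	25	44	44	0.17	0.24	XY1Y2	b16
Rodentia	Muridae	Taterillus	tranieri	14	15	24	23	0.29	0.47	XY1Y2	b18
Chiroptera	Phyllostomidae	Artibeus	jamaicensis	30	31	50	51	0.33	0.35	XY1Y2	b81
Chiroptera	Phyllostomidae	Artibeus	lituratus	30	31	50	51	0.33	0.35	XY1Y2	b81
Chiroptera	Phyllostomidae	Artibeus	toltecus	30	31	50	51	0.33	0.35	XY1Y2	b81
Chiroptera	Phyllostomidae	Carollia	subrufa	20	21	32	33	0.40	0.43	XY1Y2	b81
Chiroptera	Phyllostomidae	Carolia	perspicillata	20	21	32	33	0.40	0.43	XY1Y2	b81
Artiodactyla	Cervidae	Muntiacus	muntjak	6	7	10	11	0.33	0.43	XY1Y2	b80
Artiodactyla	Bovidae	Gazella	granti	30	31	60	60	0.06	0.06	XY1Y2	b19
Artiodactyla	Bovidae	Gazella	gazella	34	35	60	60	0.29	0.29	XY1Y2	b19
Artiodactyla	Bovidae	Gazella	dorcas	30	31	60	60	0.06	0.06	XY1Y2	b19
Artiodactyla	Bovidae	Gazella	spekei	32	33	60	60	0.18	0.18	XY1Y2	b19
Artiodactyla	Bovidae	Gazella	leptoceros	32	33	60	60	0.18	0.18	XY1Y2	b19
Artiodactyla	Bovidae	Gazella	subgutturosa	30	31	60	60	0.06	0.06	XY1Y2	b19
Soricomorpha	Soricidae	Sorex	araneus Race A	22	23	42	42	0.09	0.17	XY1Y2	b54
Soricomorpha	Soricidae	Sorex	gemelleus	22	23	44	44	0.00	0.09	XY1Y2	b54
Diprotodontia	Potoroidae	Potorous	tridactylus	12	13	22	22	0.17	0.31	XY1Y2	b67;b68
Diprotodontia	Macropodidae	Wallabia	bicolor	10	11	18	20	0.20	0.18	XY1Y2	b48
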