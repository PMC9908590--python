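id	level	parent_id	name	order
c-adenocarcinoma	class		Adenocarcinoma	1
c-adenoma	class		Adenoma	2
c-normal	class		Normal	3
s01	subtype	c-adenocarcinoma	Well differentiated adenocarcinoma	1
s02	subtype	c-adenocarcinoma	Moderately differentiated adenocarcinoma	2
s03	subtype	c-adenocarcinoma	Poorly differentiated adenocarcinoma	3
s04	subtype	c-adenocarcinoma	Well-moderately differentiated adenocarcinoma	4
s05	subtype	c-adenocarcinoma	Moderately-poorly differentiated adenocarcinoma	5
s06	subtype	c-adenocarcinoma	Tumor invasion	6
s07	subtype	c-adenocarcinoma	Tumor budding	7
s08	subtype	c-adenocarcinoma	Vascular invasion	8
s09	subtype	c-adenocarcinoma	Nerve invasion	9
s10	subtype	c-adenoma	Low-grade adenoma	10
s11	subtype	c-adenoma	High-grade adenoma	11
s12	subtype	c-normal	Normal	12
r01	reason	s01	Well-formed glandular structures [synthetic placeholder]	1
r02	reason	s01	Glands lined by near-uniform columnar cells [synthetic placeholder]	2
r03	reason	s01	Scant desmoplastic stroma [synthetic placeholder]	3
r04	reason	s02	Cribriform	4
r05	reason	s02	Irregular glandular duct arrangement	5
r06	reason	s02	Round nucleus of tumor cells	6
r07	reason	s02	Nucleoli more prominent	7
r08	reason	s02	Necrosis	8
r09	reason	s02	Papillary arrangement	9
r10	reason	s02	Rod-shaped tumor cells	10
r11	reason	s02	Stratified arrangement of tumor cells	11
r12	reason	s02	Polar disorder	12
r13	reason	s02	Mitosis visible	13
r14	reason	s02	Chromatin condensation of cells	14
r15	reason	s02	Oval nucleus	15
r16	reason	s03	Irregular arrangement of glands	16
r17	reason	s03	Mucinous differentiation	17
r18	reason	s03	Vacuolated nuclei	18
r19	reason	s03	Markedly reduced cytoplasm	19
r20	reason	s03	Karyorrhexis	20
r21	reason	s03	Thickened chromatin	21
r22	reason	s03	Screen mesh	22
r23	reason	s04	Mixed well and moderate differentiation zones [synthetic placeholder]	23
r24	reason	s05	Mixed moderate and poor differentiation zones [synthetic placeholder]	24
r25	reason	s06	Infiltration of single or several tumor cells	25
r26	reason	s06	Invasion into the muscularis mucosae	26
r27	reason	s06	Infiltration into the submucosa	27
r28	reason	s07	Tumor budding (grade 1)	28
r29	reason	s07	Tumor budding (grade 2) [synthetic placeholder]	29
r30	reason	s07	Tumor budding (grade 3) [synthetic placeholder]	30
r31	reason	s08	Tumor cells within vascular lumen [synthetic placeholder]	31
r32	reason	s08	Tumor thrombus in lymphovascular space [synthetic placeholder]	32
r33	reason	s09	Tumor surrounding nerve sheath [synthetic placeholder]	33
r34	reason	s09	Perineural tumor infiltration [synthetic placeholder]	34
r35	reason	s10	Low-grade intraepithelial neoplasia	35
r36	reason	s10	Glands lack mature differentiation	36
r37	reason	s10	Nuclei remain polar	37
r38	reason	s10	Rod-shaped nuclei	38
r39	reason	s10	Stratified or pseudostratified arrangement of nuclei	39
r40	reason	s10	Increased layers of epithelial cells	40
r41	reason	s10	Tubular structure	41
r42	reason	s10	Increased epithelial cell hierarchy	42
r43	reason	s10	Elongated crowded glands [synthetic placeholder]	43
r44	reason	s10	Mild nuclear enlargement [synthetic placeholder]	44
r45	reason	s10	Preserved goblet cells [synthetic placeholder]	45
r46	reason	s10	Basally located nuclei [synthetic placeholder]	46
r47	reason	s10	Villous surface configuration [synthetic placeholder]	47
r48	reason	s11	High-grade intraepithelial neoplasia [synthetic placeholder]	48
r49	reason	s11	Marked nuclear pleomorphism [synthetic placeholder]	49
r50	reason	s11	Loss of nuclear polarity [synthetic placeholder]	50
r51	reason	s11	Complex glandular architecture [synthetic placeholder]	51
r52	reason	s11	Back-to-back gland crowding [synthetic placeholder]	52
r53	reason	s11	Rounded vesicular nuclei [synthetic placeholder]	53
r54	reason	s11	Frequent mitotic figures [synthetic placeholder]	54
r55	reason	s11	Loss of goblet cells [synthetic placeholder]	55
r56	reason	s11	Nuclear stratification to surface [synthetic placeholder]	56
r57	reason	s11	Prominent nucleoli in dysplastic cells [synthetic placeholder]	57
r58	reason	s11	Irregular luminal contours [synthetic placeholder]	58
r59	reason	s11	Focal cribriforming within adenoma [synthetic placeholder]	59
r60	reason	s12	Fatty tissue	60
r61	reason	s12	Smooth muscle	61
r62	reason	s12	Lymphatic vessel	62
r63	reason	s12	Normal colonic crypts [synthetic placeholder]	63
r64	reason	s12	Regular goblet cells [synthetic placeholder]	64
r65	reason	s12	Lamina propria without infiltrate [synthetic placeholder]	65
r66	reason	s12	Muscularis mucosae intact [synthetic placeholder]	66
r67	reason	s12	Submucosal vessels unremarkable [synthetic placeholder]	67
r68	reason	s12	Lymphoid follicle [synthetic placeholder]	68
r69	reason	s12	Surface epithelium intact [synthetic placeholder]	69
r70	reason	s12	Uniform basal nuclei [synthetic placeholder]	70
r71	reason	s12	Paneth cells at crypt base [synthetic placeholder]	71
r72	reason	s12	Nerve plexus unremarkable [synthetic placeholder]	72
r73	reason	s12	Serosal surface smooth [synthetic placeholder]	73
r74	reason	s12	Mesothelial lining intact [synthetic placeholder]	74
r75	reason	s12	Ganglion cells present [synthetic placeholder]	75
r76	reason	s12	Mucosal vascular pattern regular [synthetic placeholder]	76
r77	reason	s12	Crypt spacing regular [synthetic placeholder]	77
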