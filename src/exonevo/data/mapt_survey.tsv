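# Curated cross-species MAPT region-homology survey.
# Percent identities are pairwise global-alignment identities of each
# species' MAPT (or the named region of it) against the human reference
# carrying the matching big-exon variant; sizes are region lengths in aa.
# variant = which big-exon variant the analyzed entry carries (4a, 4a-L,
# or blank when the region row does not depend on the variant).
# Species with two analyzed entries (e.g. carp) appear once per variant.
clade	species	variant	region	identity_pct	size_aa
primates	human	4a	full	100	776
primates	human	4a	exon4a	100	251
primates	human	4a	MTBD_9_13	100
primates	human	4a-L	full	100	833
primates	human	4a-L	exon4aL	100	355
primates	chimp	4a	full	99	776
primates	chimp	4a	Nterm_1_4	100
primates	chimp	4a	exon4a	99	251
primates	chimp	4a	MTBD_9_13	100
primates	chimp	4a-L	exon4aL	98	355
primates	gorilla	4a	full	99	756
primates	gorilla	4a	Nterm_1_4	98
primates	gorilla	4a	exon4a	98	251
primates	gorilla	4a	MTBD_9_13	100
primates	gorilla	4a-L	exon4aL	98	353
primates	gibbon	4a	full	97	780
primates	gibbon	4a	Nterm_1_4	97
primates	gibbon	4a	exon4a	94	251
primates	gibbon	4a	MTBD_9_13	100
primates	baboon	4a	full	94	780
primates	baboon	4a	Nterm_1_4	95
primates	baboon	4a	exon4a	90	251
primates	baboon	4a	MTBD_9_13	99
primates	baboon	4a-L	exon4aL	90	355
primates	marmoset	4a-L	full	85	852
primates	marmoset	4a-L	Nterm_1_4	90
primates	marmoset	4a-L	exon4aL	81	355
primates	marmoset	4a-L	MTBD_9_13	99
primates	lemur	4a	full	81	767
primates	lemur	4a	Nterm_1_4	85
primates	lemur	4a	exon4a	64	251
primates	lemur	4a	MTBD_9_13	98
mammals	cat	4a	full	84	778
mammals	cat	4a	Nterm_1_4	86
mammals	cat	4a	exon4a	70	248
mammals	cat	4a	MTBD_9_13	98
mammals	elephant	4a	full	75	760
mammals	elephant	4a	Nterm_1_4	83
mammals	elephant	4a	exon4a	65	264
mammals	elephant	4a	MTBD_9_13	99
mammals	dog	4a-L	full	75	869
mammals	dog	4a-L	Nterm_1_4	87
mammals	dog	4a-L	exon4aL	64	362
mammals	dog	4a-L	MTBD_9_13	99
mammals	rat	4a	full	71	750
mammals	rat	4a	Nterm_1_4	83
mammals	rat	4a	exon4a	56	254
mammals	rat	4a	MTBD_9_13	97
mammals	mouse	4a	full	72	749
mammals	mouse	4a	Nterm_1_4	83
mammals	mouse	4a	exon4a	56	253
mammals	mouse	4a	MTBD_9_13	97
mammals	opossum	4a-L	full	46	860
mammals	opossum	4a-L	Nterm_1_4	65
mammals	opossum	4a-L	exon4aL	39	347
mammals	opossum	4a-L	MTBD_9_13	94
vertebrates	zebra_finch	4a	full	52	705
vertebrates	zebra_finch	4a	Nterm_1_4	60
vertebrates	zebra_finch	4a	exon4a	24	280
vertebrates	zebra_finch	4a	MTBD_9_13	91
vertebrates	eagle	4a	full	52	836
vertebrates	eagle	4a	Nterm_1_4	62
vertebrates	eagle	4a	exon4a	26	305
vertebrates	eagle	4a	MTBD_9_13	93
vertebrates	turtle	4a-L	full	52	828
vertebrates	turtle	4a-L	Nterm_1_4	62
vertebrates	turtle	4a-L	exon4aL	28	353
vertebrates	turtle	4a-L	MTBD_9_13	92
vertebrates	crocodile	4a-L	full	50	889
vertebrates	crocodile	4a-L	Nterm_1_4	62
vertebrates	crocodile	4a-L	exon4aL	25	364
vertebrates	crocodile	4a-L	MTBD_9_13	92
vertebrates	frog	4a	full	43	745
vertebrates	frog	4a	Nterm_1_4	38
vertebrates	frog	4a	exon4a	16	226
vertebrates	frog	4a	MTBD_9_13	80
vertebrates	toad	4a	full	41	760
vertebrates	toad	4a	Nterm_1_4	32
vertebrates	toad	4a	exon4a	15	262
vertebrates	toad	4a	MTBD_9_13	81
vertebrates	salmon	4a	full	30	731
vertebrates	salmon	4a	Nterm_1_4	20
vertebrates	salmon	4a	exon4a	17	320
vertebrates	salmon	4a	MTBD_9_13	55
vertebrates	carp	4a	full	27	687
vertebrates	carp	4a	Nterm_1_4	16
vertebrates	carp	4a	exon4a	15	208
vertebrates	carp	4a	MTBD_9_13	53
vertebrates	carp	4a-L	full	34	814
vertebrates	carp	4a-L	Nterm_1_4	16
vertebrates	carp	4a-L	exon4aL	18	400
vertebrates	carp	4a-L	MTBD_9_13	53
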