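kind	region_or_signal	ligand	genes	grouped
in	PVN	oxytocin	Oxtr	false
in	PVN	vasopressin	Avpr1a;Avpr1b	false
in	PVN	natriuretic peptide	Npr1;Npr2;Npr3	false
in	RPa	serotonin	Htr2a;Htr2c;Htr3a;Htr3b;Htr6	false
in	RPa	TRH	Trhr	false
in	CeA	somatostatin	Sstr2;Sstr3;Sstr4	false
in	CeA	CRF	Crhr1;Crhr2	false
in	BST	CRF	Crhr1;Crhr2	false
in	BST	enkephalin	Oprm1;Oprd1	false
in	LHA	orexin	Hcrtr1;Hcrtr2	false
in	LHA	MCH	Mchr1	false
in	TMN	histamine	Hrh1;Hrh2;Hrh3	false
in	NTS/AP/CVLM/LC	dopamine	Drd1;Drd2;Drd4	true
in	NTS/AP/CVLM/LC	GABA	Gabra1;Gabra2;Gabrb1;Gabbr1;Gabbr2	true
in	NTS/AP/CVLM/LC	norepinephrine	Adra1a;Adra2a;Adrb1	true
out	ACh	acetylcholine	Chat;Ache	false
out	Dopa	dopamine	Th;Ddc	false
out	NE	norepinephrine	Th;Ddc;Dbh	false
out	Epi	epinephrine	Th;Ddc;Dbh;Pnmt	false
out	GABA	GABA	Gad1;Gad2	false
out	ANP	natriuretic peptide	Nppa	false
out	tachykinin	substance P	Tac1	false
out	somatostatin	somatostatin	Sst	false
out	CART	CART peptide	Cartpt	false
out	CCK	cholecystokinin	Cck	false
out	follistatin-like 1	FSTL1	Fstl1	false
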