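# Curated two-level taxonomy of routes of administration (reference decision set, v1).
# Columns: domain, primary, class (secondary ROA), term, is_seed.
domain	primary	class	term	is_seed
roa	Ingestion	Oral	bolus	0
roa	Ingestion	Oral	buccal	0
roa	Ingestion	Oral	gulp	0
roa	Ingestion	Oral	mouth	0
roa	Ingestion	Oral	mouthful	0
roa	Ingestion	Oral	oral	1
roa	Ingestion	Oral	orally	0
roa	Ingestion	Oral	swallow	1
roa	Ingestion	Sublingual	sublingual	1
roa	Ingestion	Sublingual	sublingually	0
roa	Ingestion	Sublingual	tongue	0
roa	Ingestion	Sublingual	tounge	0
roa	Ingestion	Drink	chug	0
roa	Ingestion	Drink	drink	0
roa	Ingestion	Drink	pour	0
roa	Ingestion	Drink	pourin	0
roa	Ingestion	Drink	sip	1
roa	Ingestion	Drink	sipper	0
roa	Ingestion	Drink	sippin	0
roa	Ingestion	Drink	swig	0
roa	Ingestion	Drink	swish	0
roa	Ingestion	Chew	chew	1
roa	Ingestion	Chew	chewy	0
roa	Ingestion	Chew	chomp	0
roa	Ingestion	Chew	gum	0
roa	Ingestion	General ingestion	ingest	1
roa	Ingestion	General ingestion	ingestion	0
roa	Inhalation	Intranasal	intranasal	0
roa	Inhalation	Intranasal	intranasally	0
roa	Inhalation	Intranasal	nasal	0
roa	Inhalation	Intranasal	nasally	0
roa	Inhalation	Intranasal	nose	0
roa	Inhalation	Intranasal	nostril	0
roa	Inhalation	Intranasal	rail	0
roa	Inhalation	Intranasal	sniff	1
roa	Inhalation	Intranasal	sniffer	0
roa	Inhalation	Intranasal	sniffin	0
roa	Inhalation	Intranasal	snoot	0
roa	Inhalation	Intranasal	snooter	0
roa	Inhalation	Intranasal	snort	1
roa	Inhalation	Intranasal	snorter	0
roa	Inhalation	Intranasal	tooter	0
roa	Inhalation	General inhalation	breath	0
roa	Inhalation	General inhalation	breathe	0
roa	Inhalation	General inhalation	dab	0
roa	Inhalation	General inhalation	exhale	0
roa	Inhalation	General inhalation	inhalation	0
roa	Inhalation	General inhalation	inhale	1
roa	Inhalation	General inhalation	insufflate	0
roa	Inhalation	General inhalation	insufflated	0
roa	Inhalation	General inhalation	insufflating	0
roa	Inhalation	General inhalation	insufflation	0
roa	Inhalation	General inhalation	puff	0
roa	Inhalation	General inhalation	toke	0
roa	Inhalation	General inhalation	tokes	0
roa	Inhalation	General inhalation	vap	0
roa	Inhalation	General inhalation	vape	0
roa	Inhalation	General inhalation	vaped	0
roa	Inhalation	General inhalation	vapes	0
roa	Inhalation	General inhalation	vaping	0
roa	Inhalation	General inhalation	vapor	0
roa	Inhalation	General inhalation	vaporise	0
roa	Inhalation	General inhalation	vaporize	0
roa	Inhalation	General inhalation	vaporizer	0
roa	Inhalation	General inhalation	vapour	0
roa	Inhalation	Smoking	bong	0
roa	Inhalation	Smoking	fume	0
roa	Inhalation	Smoking	hookah	0
roa	Inhalation	Smoking	pipe	0
roa	Inhalation	Smoking	smoke	1
roa	Inhalation	Smoking	smoker	0
roa	Inhalation	Smoking	smokin	0
roa	Inhalation	Smoking	spliff	0
roa	Injection	Intramuscular	deltoid	0
roa	Injection	Intramuscular	imed	0
roa	Injection	Intramuscular	iming	0
roa	Injection	Intramuscular	intramuscular	1
roa	Injection	Intramuscular	intramuscularly	0
roa	Injection	Subcutaneous	subcutaneous	1
roa	Injection	Subcutaneous	subcutaneously	0
roa	Injection	Subcutaneous	subq	0
roa	Injection	Intravenous	arterial	0
roa	Injection	Intravenous	bloodstream	0
roa	Injection	Intravenous	intravenous	1
roa	Injection	Intravenous	intravenously	0
roa	Injection	Intravenous	iv	0
roa	Injection	Intravenous	ivd	0
roa	Injection	Intravenous	ived	0
roa	Injection	Intravenous	iving	0
roa	Injection	Intravenous	ivs	0
roa	Injection	Intravenous	vein	0
roa	Injection	Intravenous	venous	0
roa	Injection	General injection	bang	0
roa	Injection	General injection	inject	1
roa	Injection	General injection	injectable	0
roa	Injection	General injection	injection	0
roa	Injection	General injection	parenteral	0
roa	Injection	General injection	shoot	0
roa	Injection	General injection	shot	0
roa	Rectally	Rectally	anal	0
roa	Rectally	Rectally	anally	0
roa	Rectally	Rectally	boof	0
roa	Rectally	Rectally	boofed	0
roa	Rectally	Rectally	boofing	0
roa	Rectally	Rectally	bunghole	0
roa	Rectally	Rectally	butt	0
roa	Rectally	Rectally	pooper	0
roa	Rectally	Rectally	rectal	1
roa	Rectally	Rectally	rectally	0
roa	Other ROA	Dermal	cutaneous	0
roa	Other ROA	Dermal	dermis	0
roa	Other ROA	Dermal	transdermal	1
roa	Other ROA	Dermal	transdermally	0
roa	Other ROA	Urogenital	vaginal	0
roa	Other ROA	Intrathecal	intrathecal	0
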