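# Curated vocabulary of opioid substances (reference decision set, v1).
# Columns: domain, primary, class, term, is_seed. Seeds are the literature-derived query terms.
domain	primary	class	term	is_seed
substance		heroin	bth	1
substance		heroin	diacetylmorphine	0
substance		heroin	diamorphine	0
substance		heroin	dope	0
substance		heroin	ecp	1
substance		heroin	goofball	0
substance		heroin	goofballs	0
substance		heroin	gunpowder	0
substance		heroin	h	0
substance		heroin	herion	1
substance		heroin	heroin	1
substance		heroin	heroine	0
substance		heroin	heron	0
substance		heroin	smack	0
substance		heroin	speedball	0
substance		heroin	speedballing	0
substance		heroin	speedballs	1
substance		heroin	tar	0
substance		buprenorphine	bup	0
substance		buprenorphine	bupe	1
substance		buprenorphine	buprenorphine	1
substance		buprenorphine	butrans	1
substance		buprenorphine	sub	0
substance		buprenorphine	suboxone	1
substance		buprenorphine	subutex	1
substance		buprenorphine	zub	0
substance		buprenorphine	zubsolv	1
substance		hydrocodone	hydro	0
substance		hydrocodone	hydrocodone	1
substance		hydrocodone	hydrocodones	1
substance		hydrocodone	lortab	1
substance		hydrocodone	lortabs	1
substance		hydrocodone	norco	1
substance		hydrocodone	norcos	1
substance		hydrocodone	tuss	0
substance		hydrocodone	tussionex	1
substance		hydrocodone	vic	0
substance		hydrocodone	vicoden	0
substance		hydrocodone	vicodin	1
substance		hydrocodone	vicodins	1
substance		hydrocodone	vicoprofen	1
substance		hydrocodone	vics	1
substance		hydrocodone	vikes	0
substance		hydrocodone	viks	0
substance		hydrocodone	zohydro	1
substance		codeine	cocodamol	0
substance		codeine	codein	1
substance		codeine	codeine	1
substance		codeine	codiene	1
substance		codeine	codine	0
substance		codeine	dhc	0
substance		codeine	dihydrocodeine	1
substance		codeine	prometh	0
substance		codeine	sizzurp	0
substance		codeine	syrup	0
substance		oxymorphone	g74	0
substance		oxymorphone	opana	1
substance		oxymorphone	opanas	0
substance		oxymorphone	oxymorphone	1
substance		oxymorphone	panda	0
substance		tramadol	desmethyltramadol	0
substance		tramadol	dsmt	0
substance		tramadol	tram	0
substance		tramadol	tramadol	1
substance		tramadol	ultram	1
substance		hydromorphone	dil	0
substance		hydromorphone	dilauded	0
substance		hydromorphone	dilaudid	1
substance		hydromorphone	dilaudids	0
substance		hydromorphone	dillies	1
substance		hydromorphone	dilly	0
substance		hydromorphone	dillys	0
substance		hydromorphone	diluadid	1
substance		hydromorphone	hydromorph	1
substance		hydromorphone	hydromorphone	1
substance		oxycodone	15s	0
substance		oxycodone	30s	0
substance		oxycodone	codone	0
substance		oxycodone	contin	0
substance		oxycodone	ms	0
substance		oxycodone	oc	0
substance		oxycodone	ocs	0
substance		oxycodone	oxy	1
substance		oxycodone	oxycodone	1
substance		oxycodone	oxycontin	1
substance		oxycodone	oxycontins	0
substance		oxycodone	oxycotin	1
substance		oxycodone	oxys	1
substance		oxycodone	perc	1
substance		oxycodone	percocet	1
substance		oxycodone	percocets	1
substance		oxycodone	percoset	0
substance		oxycodone	percosets	0
substance		oxycodone	percs	1
substance		oxycodone	perk	0
substance		oxycodone	roxi	1
substance		oxycodone	roxicodone	1
substance		oxycodone	roxie	1
substance		oxycodone	roxies	1
substance		oxycodone	roxis	1
substance		oxycodone	roxy	1
substance		oxycodone	roxycodone	1
substance		oxycodone	roxys	1
substance		morphine	kadian	0
substance		morphine	morph	0
substance		morphine	morphine	1
substance		fentanyl	acetylfentanyl	1
substance		fentanyl	butyr	0
substance		fentanyl	butyrfentanyl	0
substance		fentanyl	carf	0
substance		fentanyl	carfent	0
substance		fentanyl	carfentanil	1
substance		fentanyl	carfentanyl	0
substance		fentanyl	duragesic	1
substance		fentanyl	fent	1
substance		fentanyl	fentanyl	1
substance		fentanyl	fents	0
substance		fentanyl	fentynal	0
substance		fentanyl	fetanyl	0
substance		fentanyl	furanyl	0
substance		fentanyl	sufentanil	0
substance		fentanyl	u47700	0
substance		antagonist	nalaxone	1
substance		antagonist	naloxone	1
substance		antagonist	naltrexone	0
substance		antagonist	narcan	1
substance		antagonist	narcon	0
substance		antagonist	revia	0
substance		antagonist	viv	0
substance		antagonist	vivitrol	1
substance		methadone	mdone	0
substance		methadone	methadone	1
substance		methadone	methodone	1
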