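# Curated vocabulary of drug-tampering methods (reference decision set, v1).
# Columns: domain, primary, class (transformation), term, is_seed.
domain	primary	class	term	is_seed
tampering		Brew	brew	1
tampering		Brew	brewer	0
tampering		Brew	homebrew	1
tampering		Concentrate	concentrate	1
tampering		Concentrate	concentration	0
tampering		Concentrate	purify	0
tampering		Dissolve	desolve	0
tampering		Dissolve	dilute	0
tampering		Dissolve	disolve	0
tampering		Dissolve	disolved	0
tampering		Dissolve	disolves	0
tampering		Dissolve	dissolve	1
tampering		Dissolve	solute	0
tampering		Dissolve	solution	0
tampering		Dissolve	soluble	0
tampering		Dissolve	soluable	0
tampering		Evaporate	evap	0
tampering		Evaporate	evaporate	0
tampering		Extract	cwe	1
tampering		Extract	extract	1
tampering		Extract	extraction	0
tampering		Grind	chop	0
tampering		Grind	crush	1
tampering		Grind	crushable	0
tampering		Grind	crusher	0
tampering		Grind	grind	1
tampering		Grind	grinded	0
tampering		Grind	grinder	0
tampering		Grind	ground	0
tampering		Grind	pulverize	0
tampering		Heat	boil	0
tampering		Heat	heat	1
tampering		Heat	melt	0
tampering		Heat	microwave	0
tampering		Heat	overheat	0
tampering		Heat	simmer	0
tampering		Infusion	infuse	0
tampering		Infusion	infusion	1
tampering		Infusion	tea	0
tampering		Infusion	tincture	0
tampering		Peel	peal	0
tampering		Peel	peel	0
tampering		Peel	shave	0
tampering		Soak	soak	1
tampering		Soak	submerge	0
tampering		Wash	rewash	0
tampering		Wash	rinse	0
tampering		Wash	wash	0
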