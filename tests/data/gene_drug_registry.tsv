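gene	drug	qualifier
CYP2B6	efavirenz
CYP2C19	amitriptyline
CYP2C19	citalopram
CYP2C19	clobazam
CYP2C19	clomipramine
CYP2C19	clopidogrel
CYP2C19	doxepin
CYP2C19	escitalopram
CYP2C19	esomeprazole
CYP2C19	imipramine
CYP2C19	lansoprazole
CYP2C19	omeprazole
CYP2C19	pantoprazole
CYP2C19	prasugrel
CYP2C19	sertraline
CYP2C19	ticagrelor
CYP2C19	trimipramine
CYP2C19	voriconazole
CYP2C9	aspirin
CYP2C9	celecoxib
CYP2C9	flurbiprofen
CYP2C9	ibuprofen
CYP2C9	lornoxicam
CYP2C9	meloxicam
CYP2C9	naproxen
CYP2C9	phenytoin
CYP2C9	piroxicam
CYP2C9	tenoxicam
CYP2C9	warfarin
CYP2D6	amiodarone
CYP2D6	amitriptyline
CYP2D6	amphetamine
CYP2D6	aripiprazole
CYP2D6	atenolol
CYP2D6	atomoxetine
CYP2D6	bisoprolol
CYP2D6	brexpiprazole
CYP2D6	cavedilol
CYP2D6	clomipramine
CYP2D6	clonidine
CYP2D6	clozapine
CYP2D6	codeine
CYP2D6	desipramine
CYP2D6	doxepin
CYP2D6	duloxetine
CYP2D6	eliglustat
CYP2D6	flecainide
CYP2D6	fluoxetine
CYP2D6	fluphenazine
CYP2D6	fluvoxamine
CYP2D6	haloperidol
CYP2D6	hydrocodone
CYP2D6	iloperidone
CYP2D6	imipramine
CYP2D6	methylphenidate
CYP2D6	metoprolol
CYP2D6	mirtazapine
CYP2D6	moclobemide
CYP2D6	nebivolol
CYP2D6	nortriptyline
CYP2D6	odansetron
CYP2D6	olanzapine
CYP2D6	oxycodone
CYP2D6	paroxetine
CYP2D6	perphenazine
CYP2D6	pimozide
CYP2D6	propafenone
CYP2D6	propranolol
CYP2D6	quetiapine
CYP2D6	risperidone
CYP2D6	tamoxifen
CYP2D6	tetrabenazine
CYP2D6	tramadol
CYP2D6	tropisetron
CYP2D6	trimipramine
CYP2D6	venlafaxine
CYP2D6	vortioxetine
CYP2D6	zuclopenthixol
CYP3A5	tacrolimus
HLA-A	carbamazepine	*31:01
HLA-B	abacavir	*57:01
HLA-B	allopurinol	*58:01
HLA-B	carbamazepine	*15:02
HLA-B	oxcarbazepine	*15:02
HLA-B	phenytoin	*15:02
NUDT15	azathioprine
NUDT15	mercaptopurine
NUDT15	thioguanine
SLCO1B1	atorvastatin
SLCO1B1	fluvastatin
SLCO1B1	rosuvastatin
SLCO1B1	simvastatin
TPMT	azathioprine
TPMT	mercaptopurine
TPMT	thioguanine
VKORC1	acenocoumarol
VKORC1	warfarin
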