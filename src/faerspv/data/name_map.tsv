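# Verbatim FAERS drug name -> active ingredient (tab-delimited).
# Editable; extend for your own extract. The EXCLUDE value drops a name
# as too ambiguous to attribute to any ingredient.
AVANDIA	rosiglitazone
ROSIGLITAZONE MALEATE	rosiglitazone
ROSIGLITIZONE	rosiglitazone
AVANDAMET	metformin and rosiglitazone
ACTOS	pioglitazone
GLUCOPHAGE	metformin
METFORMIN HCL	metformin
METFORMIN HYDROCHLORIDE	metformin
ONGLYZA	saxagliptin
KOMBIGLYZE XR	metformin and saxagliptin
KOMBIGLYZE	metformin and saxagliptin
HUMALOG	insulin lispro
LANTUS	insulin glargine
JANUVIA	sitagliptin
FARXIGA	dapagliflozin
JARDIANCE	empagliflozin
ENTRESTO	sacubitril valsartan
SACUBITRIL/VALSARTAN	sacubitril valsartan
HUMIRA	adalimumab
REMICADE	infliximab
ENBREL	etanercept
REVLIMID	lenalidomide
VIOXX	rofecoxib
CELEBREX	celecoxib
LETAIRIS	ambrisentan
VOLIBRIS	ambrisentan
OPSUMIT	macitentan
TRACLEER	bosentan
REMODULIN	treprostinil
VYNDAQEL	tafamidis
VYNDAMAX	tafamidis
PRADAXA	dabigatran etexilate
DABIGATRAN	dabigatran etexilate
ELIQUIS	apixaban
XARELTO	rivaroxaban
COUMADIN	warfarin
PLAVIX	clopidogrel
AGGRASTAT	tirofiban
ASPIRIN	acetylsalicylic acid
ADRIAMYCIN	doxorubicin
DOXORUBICIN HCL	doxorubicin
KYPROLIS	carfilzomib
VELCADE	bortezomib
KEYTRUDA	pembrolizumab
OPDIVO	nivolumab
GLEEVEC	imatinib
IMATINIB MESYLATE	imatinib
AVASTIN	bevacizumab
HERCEPTIN	trastuzumab
TAGRISSO	osimertinib
RITUXAN	rituximab
SUTENT	sunitinib
TAXOL	paclitaxel
CYTOXAN	cyclophosphamide
EFFEXOR	venlafaxine
VENLAFAXINE HCL	venlafaxine
VENLAFAXINE HYDROCHLORIDE	venlafaxine
LIPITOR	atorvastatin
NORVASC	amlodipine
LASIX	furosemide
LANOXIN	digoxin
PLAQUENIL	hydroxychloroquine
DELTASONE	prednisone
ADVIL	ibuprofen
ALEVE	naproxen
UNKNOWN MEDICATION	EXCLUDE
UNKNOWN	EXCLUDE
INVESTIGATIONAL DRUG	EXCLUDE
BLINDED THERAPY	EXCLUDE
MULTIPLE DRUGS	EXCLUDE
ALL OTHER THERAPEUTIC PRODUCTS	EXCLUDE
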