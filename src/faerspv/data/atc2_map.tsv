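# Active ingredient -> WHO ATC level-2 therapeutic subgroup (tab-delimited).
# Multiple rows per ingredient are allowed; combination products are their
# own entries. Editable; covers common cardiotoxicity-relevant ingredients.
rosiglitazone	A10
pioglitazone	A10
metformin	A10
metformin and rosiglitazone	A10
metformin and saxagliptin	A10
saxagliptin	A10
sitagliptin	A10
dapagliflozin	A10
empagliflozin	A10
insulin lispro	A10
insulin glargine	A10
sacubitril valsartan	C09
valsartan	C09
ramipril	C09
lisinopril	C09
adalimumab	L04
infliximab	L04
etanercept	L04
lenalidomide	L04
rofecoxib	M01
celecoxib	M01
ibuprofen	M01
naproxen	M01
ambrisentan	C02
macitentan	C02
bosentan	C02
treprostinil	B01
dabigatran etexilate	B01
apixaban	B01
rivaroxaban	B01
warfarin	B01
clopidogrel	B01
tirofiban	B01
acetylsalicylic acid	B01
acetylsalicylic acid	N02
tafamidis	N07
doxorubicin	L01
carfilzomib	L01
bortezomib	L01
pembrolizumab	L01
nivolumab	L01
imatinib	L01
bevacizumab	L01
trastuzumab	L01
osimertinib	L01
rituximab	L01
sunitinib	L01
paclitaxel	L01
cisplatin	L01
cyclophosphamide	L01
venlafaxine	N06
atorvastatin	C10
furosemide	C03
digoxin	C01
amlodipine	C08
hydroxychloroquine	P01
prednisone	H02
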