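metabolite_a	metabolite_b
inosine	hypoxanthine
hypoxanthine	xanthine
uridine	uracil
uracil	5,6-dihydrouracil
glucose	UDP-glucose
UDP-glucose	UDP-galactose
uridine	UDP-glucose
glucose	pyruvate
glucose	lactate
pyruvate	lactate
pyruvate	alanine
pyruvate	acetate
pyruvate	citrate
citrate	succinate
succinate	fumarate
fumarate	aspartate
tyrosine	fumarate
glutamate	glutamine
glutamate	GABA
GABA	succinate
glutamate	glutathione
glycine	glutathione
glycine	sarcosine
betaine	sarcosine
choline	betaine
choline	phosphocholine
phosphocholine	sn-glycero-3-phosphocholine
phosphoethanolamine	phosphocholine
valine	3-hydroxyisobutyrate
3-hydroxybutyrate	acetoacetate
acetoacetate	acetone
NAD+	niacinamide
NAD+	NADPH
histidine	histamine
histidine	glutamate
phenylalanine	tyrosine
ethanol	acetate
methanol	formate
glycine	formate
glycine	creatine
glutamate	aspartate
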