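metabolite	window_lo	window_hi	weight
leucine	0.952	0.972	1
isoleucine	1.002	1.022	1
valine	1.028	1.103	1
ethanol	1.117	1.192	1
3-hydroxybutyrate	1.198	1.267	1
lactate	1.273	1.393	1
alanine	1.417	1.543	1
lysine	1.657	1.783	1
acetate	1.912	1.983	1
glutamate	2.017	2.107	1
succinate	2.383	2.427	1
glutamine	2.433	2.497	1
glutathione	2.503	2.597	1
5,6-dihydrouracil	2.603	2.662	1
dimethylamine	2.703	2.737	1
sarcosine	2.743	2.777	1
aspartate	2.783	2.863	1
creatine	2.998	3.103	1
choline	3.127	3.202	1
phosphocholine	3.208	3.232	1
sn-glycero-3-phosphocholine	3.238	3.313	1
glycine	3.518	3.607	1
betaine	3.873	3.912	1
phosphoethanolamine	3.958	4.042	1
glucose	5.167	5.293	1
UDP-glucose	5.537	5.622	1
UDP-galactose	5.628	5.713	1
uracil	5.737	5.847	1
uridine	5.853	5.963	1
fumarate	6.457	6.583	1
tyrosine	6.837	6.963	1
phenylalanine	7.267	7.482	1
histidine	7.737	7.842	1
xanthine	7.848	7.917	1
hypoxanthine	8.127	8.222	1
inosine	8.278	8.377	1
NADPH	8.537	8.657	1
niacinamide	8.877	9.003	1
NAD+	9.077	9.403	1
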