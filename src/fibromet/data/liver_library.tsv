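metabolite	center_ppm	rel_height	halfwidth_ppm
isoleucine	0.94	3.0	0.003
isoleucine	1.01	3.0	0.003
leucine	0.96	6.0	0.003
valine	0.99	3.0	0.003
valine	1.04	3.0	0.003
valine	2.26	1.0	0.003
ethanol	1.18	3.0	0.003
ethanol	3.66	2.0	0.003
3-hydroxybutyrate	1.21	3.0	0.003
3-hydroxybutyrate	2.31	1.0	0.003
3-hydroxybutyrate	4.16	1.0	0.003
lactate	1.33	3.0	0.003
lactate	4.11	1.0	0.003
alanine	1.48	3.0	0.003
alanine	3.78	1.0	0.003
lysine	1.72	2.0	0.003
lysine	1.9	2.0	0.003
acetate	1.92	3.0	0.003
glutamate	2.08	2.0	0.003
glutamate	2.35	2.0	0.003
glutamine	2.14	2.0	0.003
glutamine	2.45	2.0	0.003
succinate	2.41	4.0	0.003
glutathione	2.17	2.0	0.003
glutathione	2.55	2.0	0.003
glutathione	2.95	2.0	0.003
5,6-dihydrouracil	2.65	2.0	0.003
aspartate	2.68	1.0	0.003
aspartate	2.8	1.0	0.003
dimethylamine	2.72	6.0	0.003
sarcosine	2.76	3.0	0.003
creatine	3.04	3.0	0.003
creatine	3.93	2.0	0.003
choline	3.19	9.0	0.003
phosphocholine	3.22	9.0	0.003
phosphocholine	4.21	2.0	0.003
sn-glycero-3-phosphocholine	3.25	9.0	0.003
sn-glycero-3-phosphocholine	4.32	2.0	0.003
betaine	3.9	2.0	0.003
glucose	3.4	2.0	0.003
glucose	3.47	2.0	0.003
glucose	3.72	3.0	0.003
glucose	3.84	2.0	0.003
glucose	5.23	1.5	0.003
glycine	3.56	2.0	0.003
phosphoethanolamine	3.98	3.0	0.003
uracil	5.8	1.0	0.003
uracil	7.54	1.0	0.003
uridine	5.9	2.0	0.003
inosine	6.1	1.0	0.003
inosine	8.24	1.0	0.003
inosine	8.34	1.0	0.003
UDP-glucose	5.6	1.0	0.003
UDP-glucose	7.95	1.0	0.003
UDP-galactose	5.65	1.0	0.003
NAD+	8.42	1.0	0.003
NAD+	9.14	1.0	0.003
NAD+	9.34	1.0	0.003
fumarate	6.52	2.0	0.003
tyrosine	6.9	2.0	0.003
tyrosine	7.19	2.0	0.003
histidine	7.09	1.0	0.003
histidine	7.8	1.0	0.003
phenylalanine	7.33	2.0	0.003
phenylalanine	7.37	3.0	0.003
phenylalanine	7.43	2.0	0.003
niacinamide	7.6	1.0	0.003
niacinamide	8.72	1.0	0.003
niacinamide	8.94	1.0	0.003
xanthine	7.89	1.0	0.003
hypoxanthine	8.19	1.0	0.003
hypoxanthine	8.21	1.0	0.003
NADPH	6.18	1.0	0.003
NADPH	8.6	1.0	0.003
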