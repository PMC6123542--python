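metabolite	model_vs_control	low_vs_model	medium_vs_model	high_vs_model
hypoxanthine	-1.11	0.06	-0.32	-0.43
inosine	-1.06	0.7	-0.12	1.25
xanthine	-1.04	0.06	-0.32	-0.43
fumarate	-0.96	0.11	0.38	0.44
glucose	-0.77	0.07	0.01	-0.17
niacinamide	-0.68	-0.12	-0.04	-0.07
NADPH	-0.57	0.26	-0.01	0
3-hydroxybutyrate	-0.57	0.14	-0.18	0.01
tyrosine	-0.43	-0.07	-0.07	-0.76
histidine	-0.37	-0.14	0.19	0.04
NAD+	-0.28	0.39	-0.03	0.28
isoleucine	-0.23	0.06	-0.17	-0.47
lysine	-0.21	-0.22	-0.15	-0.45
leucine	-0.19	-0.06	-0.18	-0.67
creatine	-0.17	-0.12	-0.09	-0.04
choline	-0.14	0.2	-0.12	-0.22
acetate	-0.1	0.12	-0.07	0.18
valine	-0.09	-0.03	-0.18	-0.69
phenylalanine	0.05	0.04	-0.03	-0.81
betaine	0.11	-0.07	0.3	0.08
5,6-dihydrouracil	0.15	0.18	0	0.06
glycine	0.27	-0.18	-0.3	-0.4
glutamate	0.29	-0.15	-0.09	-0.17
uridine	0.29	0.26	0.04	0.42
uracil	0.33	-0.14	0.29	-0.25
aspartate	0.33	-0.29	-0.17	-0.27
ethanol	0.39	-0.94	-0.56	-1.22
glutamine	0.43	0.15	0.06	0.37
alanine	0.49	-0.09	-0.12	-0.3
dimethylamine	0.52	-0.22	-0.17	-0.15
UDP-galactose	0.53	0.41	0.15	0.67
glutathione	0.54	0.03	-0.06	0.32
succinate	0.57	-0.14	-0.3	-0.2
sn-glycero-3-phosphocholine	0.59	0.1	0.16	0.2
sarcosine	0.63	0.18	-0.04	0.06
phosphocholine	0.63	-0.07	0.06	0.19
phosphoethanolamine	1.13	0.04	0.87	0.74
UDP-glucose	1.21	0.43	0.08	0.97
lactate	1.23	-0.2	0	-0.12
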