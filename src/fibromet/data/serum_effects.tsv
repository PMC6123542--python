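metabolite	model_vs_control	low_vs_model	medium_vs_model	high_vs_model
succinate	-0.74	-0.23	-0.16	-0.04
GABA	-0.57	-0.08	-0.05	0.08
3-hydroxybutyrate	-0.46	-0.04	0.02	0.2
glucose	-0.45	0.05	0.12	0
acetoacetate	-0.32	-0.4	-0.28	-0.77
tyrosine	-0.27	0.12	0.03	0.26
tryptophan	-0.19	0.1	-0.1	0.27
3-hydroxyisobutyrate	-0.17	-0.14	0.21	0.1
uridine	-0.03	-0.14	-0.01	0.05
formate	-0.02	-0.25	-0.27	0.04
inosine	-0.01	0.03	-0.06	0.1
creatine	0.00	-0.22	-0.23	-0.04
methanol	0.02	0.12	0.04	-1.12
phenylalanine	0.04	0.06	-0.09	0.18
lysine	0.06	-0.02	-0.19	0.13
pyruvate	0.08	0.49	-0.25	0.33
glutamine	0.18	-0.08	-0.19	-0.03
acetate	0.27	-0.15	-0.28	0.13
citrate	0.31	0.02	-0.13	0.15
isoleucine	0.32	-0.08	-0.24	0.11
valine	0.41	-0.14	-0.27	0.1
ethanol	0.47	0.02	-0.13	0.15
lactate	0.53	-0.08	-0.01	0.32
alanine	0.65	0.04	-0.09	0.22
leucine	0.74	-0.13	-0.23	0.08
glycine	0.82	-0.06	-0.07	0.07
histamine	0.95	0.06	-0.07	0.13
acetone	1.01	-0.42	-0.51	-0.32
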