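metabolite	center_ppm	rel_height	halfwidth_ppm
isoleucine	0.94	3.0	0.003
isoleucine	1.01	3.0	0.003
leucine	0.96	6.0	0.003
valine	0.99	3.0	0.003
valine	1.04	3.0	0.003
3-hydroxyisobutyrate	1.07	3.0	0.003
3-hydroxybutyrate	1.21	3.0	0.003
3-hydroxybutyrate	2.31	1.0	0.003
3-hydroxybutyrate	4.16	1.0	0.003
ethanol	1.18	3.0	0.003
ethanol	3.66	2.0	0.003
lactate	1.33	3.0	0.003
lactate	4.11	1.0	0.003
alanine	1.48	3.0	0.003
alanine	3.78	1.0	0.003
lysine	1.72	2.0	0.003
lysine	1.9	2.0	0.003
acetate	1.92	3.0	0.003
glutamine	2.14	2.0	0.003
glutamine	2.45	2.0	0.003
acetone	2.23	6.0	0.003
acetoacetate	2.28	3.0	0.003
GABA	2.35	2.0	0.003
GABA	3.01	2.0	0.003
pyruvate	2.38	3.0	0.003
succinate	2.41	4.0	0.003
citrate	2.54	2.0	0.003
citrate	2.67	2.0	0.003
creatine	3.04	3.0	0.003
creatine	3.93	2.0	0.003
methanol	3.36	3.0	0.003
glucose	3.4	2.0	0.003
glucose	3.47	2.0	0.003
glucose	3.72	3.0	0.003
glucose	3.84	2.0	0.003
glucose	5.23	1.5	0.003
glycine	3.56	2.0	0.003
inosine	6.1	1.0	0.003
inosine	8.24	1.0	0.003
inosine	8.34	1.0	0.003
tyrosine	6.9	2.0	0.003
tyrosine	7.19	2.0	0.003
histamine	7.14	1.0	0.003
histamine	7.99	1.0	0.003
phenylalanine	7.33	2.0	0.003
phenylalanine	7.37	3.0	0.003
phenylalanine	7.43	2.0	0.003
tryptophan	7.54	1.0	0.003
tryptophan	7.73	1.0	0.003
uridine	5.9	2.0	0.003
uridine	7.87	1.0	0.003
formate	8.46	1.0	0.003
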