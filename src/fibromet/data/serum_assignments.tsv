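metabolite	window_lo	window_hi	weight
leucine	0.952	0.972	1
isoleucine	1.002	1.022	1
valine	1.028	1.052	1
3-hydroxyisobutyrate	1.058	1.122	1
ethanol	1.128	1.192	1
3-hydroxybutyrate	1.198	1.267	1
lactate	1.273	1.393	1
alanine	1.417	1.543	1
lysine	1.657	1.783	1
acetate	1.912	1.983	1
acetone	2.188	2.252	1
acetoacetate	2.258	2.292	1
GABA	2.333	2.362	1
pyruvate	2.368	2.392	1
succinate	2.398	2.427	1
glutamine	2.433	2.492	1
citrate	2.607	2.733	1
creatine	3.028	3.103	1
methanol	3.297	3.377	1
glycine	3.518	3.607	1
glucose	5.167	5.293	1
uridine	5.837	5.963	1
tyrosine	6.837	6.963	1
phenylalanine	7.267	7.482	1
tryptophan	7.667	7.793	1
histamine	7.933	8.053	1
inosine	8.177	8.397	1
formate	8.403	8.523	1
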