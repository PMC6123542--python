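synonym	canonical
nicotinamide	niacinamide
beta-hydroxybutyrate	3-hydroxybutyrate
b-hydroxybutyrate	3-hydroxybutyrate
3-hb	3-hydroxybutyrate
beta-hydroxyisobutyrate	3-hydroxyisobutyrate
gpc	sn-glycero-3-phosphocholine
glycerophosphocholine	sn-glycero-3-phosphocholine
glycerophosphorylcholine	sn-glycero-3-phosphocholine
nad	NAD+
nadh	NAD+
4-aminobutyrate	GABA
gamma-aminobutyrate	GABA
dihydrouracil	5,6-dihydrouracil
udpg	UDP-glucose
udp-gal	UDP-galactose
pe	phosphoethanolamine
pc	phosphocholine
dma	dimethylamine
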