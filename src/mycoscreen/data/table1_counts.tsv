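taxon	rank	n	positives
Mucoromycota	phylum	107	29
Glomeromycotina	subphylum	9	8
Mucoromycotina	subphylum	71	14
Mortierellomycotina	subphylum	27	7
Zoopagomycota	phylum	25	10
Entomophthoromycotina	subphylum	11	6
Kickxellomycotina	subphylum	11	3
Zoopagomycotina	subphylum	3	1
Blastocladiomycota	phylum	44	7
Blastocladiales	order	42	7
Physodermatales	order	2	0
Chytridiomycota	phylum	146	24
Monoblepharidales	order	5	0
Cladochytriales	order	21	10
Synchytriales	order	2	0
Chytridiales	order	40	4
Lobulomycetales	order	2	0
Rhizophydiales	order	35	5
Rhizophlyctidales	order	6	0
Spizellomycetales	order	36	5
Neocallimastigomycota	phylum	8	2
Cryptomycota	phylum	2	0
Total	total	333	72
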