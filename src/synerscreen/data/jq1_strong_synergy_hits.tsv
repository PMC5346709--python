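rank	nsc_id	R	mode	name
1	67574	0.145	M	Vincristine sulfate
2	669356	0.243	M	Cemadotin
3	153858	0.246	M	Maysanine
4	332598	0.293	M	Rhizoxin
5	330770	0.306	M	(5-Amino-1,2-dihydro-3-phenylpyrido[3,4-b]pyrazin-7-yl)-carbamic acid ethyl ester
6	301684	0.311	M	Crassin (2,12-dihydroxy-14-oxabicyclo[11.3.1]heptadeca-4,8-dien-15-one)
7	628503	0.342	M	Docetaxel
8	49842	0.38	M	Vinblastine Sulfate Hydrate
9	608210	0.359	M	Vinorelbine tartrate
10	258812	0.061	Q;IC	N,N-Dimethyldaunomycin HCl
11	659999	0.094	Q;IC	2-Bromo-5,8-dihydroxy-3-[4-[2-(2-hydroxyethoxy)ethyl]-1-piperazinyl]-naphthalene-1,4-dione HCl
12	70845	0.111	Q;IC	Nogalamycin
13	83950	0.241	Q;IC	Streptonigrin
14	102815	0.34	Q;IC	7-O-Methylnogalarol
15	265450	0.395	Q;IC	Nogamycin
16	349644	0.31	Q	Cyanocycline A
17	697726	0.34	Q	RH-1 or 2,5-Diaziridinyl-3-(hydroxymethyl)-6-methyl-1,4-benzoquinone
18	267461	0.398	Q	Nanaomycin
19	3053	0.273	IC	Dactinomycin
20	243928	0.281	IC	N-[4-(9-acridinylamino)-3-methoxyphenyl]-ethanesulfonamide monomethanesulfonate
21	526417	0.337	IC	Levomycin
22	681239	0.2	PI	Bortezomib
23	122023	0.225	ION	Valinomycin
24	754143	0.29	HDACI	Romidepsin
25	131547	0.306	ND	Marckine
26	30916	0.311	ND	MP 317 or SKI23340 or 2,5-Bis[(benzoyloxymercuri)methyl]-P-dioxane
27	126727	0.316	ND	5′-Desmethoxy-β-peltatin-A methyl ether
28	635121	0.351	ND	N'-[(1Z)-1-(1,4-benzothiazin-2-ylidene)ethyl]-2-hydroxybenzohydrazide
29	639828	0.352	ND	Antineoplastic 639828
30	175636	0.362	ND	6-Chloro-2,3-dihydro-2-(1-naphthalenyl)-4(1H)-quinazolinone
31	620358	0.373	ND	Methyl 13-hydroxy-15-oxo-kaurenoate
32	654260	0.394	ND	2-[[(2S)-2-amino-1-oxopropyl]amino]-N-[[[4-[(5-bromo-2-pyrimidinyl)oxy]-3-methylphenyl]amino]carbonyl]-benzamide HCl
33	129414	0.396	ND	(+-)-2,3-Dehydroemetine 2HCl
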