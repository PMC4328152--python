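contrast	superfamily	family	clade	eusocial	mean_n	n_species	origin
1	Apoidea	Apidae	Meliponini+Apini+Bombini	1	16.17	153	loss
1	Apoidea	Apidae	Euglossini	0	19.25	4	loss
2	Apoidea	Apidae	Meliponini+Apini+Bombini (-Euglossini)	1	16.17	153	origin
2	Apoidea	Apidae	Eucerini+Emphorini+Exomalopsini	0	11.80	5	origin
3	Apoidea	Apidae	Allodapini	1	NA	0	origin
3	Apoidea	Apidae	Allodapini solitary sister	0	NA	0	origin
4	Apoidea	Crabronidae	Microstigmus	1	3.75	4	origin
4	Apoidea	Crabronidae	Nonsocial Crabronidae	0	NA	0	origin
5	Apoidea	Halictidae	Halictus+Lasioglossum	1	13.50	8	origin
5	Apoidea	Halictidae	Agapostemon	0	17.00	1	origin
6	Apoidea	Halictidae	Augochlorini (eusocial)	1	16.00	1	origin
6	Apoidea	Halictidae	Augochlorini (solitary)	0	11.67	3	origin
7	Vespoidea	Formicidae	Formicidae	1	16.29	793	origin
7	Apoidea	Apoidea	Apoidea (all nonsocial)	0	14.48	48	origin
8	Vespoidea	Vespidae	Stenogastrinae	1	7.00	1	origin
8	Vespoidea	Vespidae	Eumeninae (-Polistinae+Vespinae)	0	7.78	9	origin
9	Vespoidea	Vespidae	Polistinae+Vespinae	1	24.48	26	origin
9	Vespoidea	Vespidae	Eumeninae	0	7.78	9	origin
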