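taxon	trophic_group	size_class	mni_eligible
Mammuthus meridionalis	herbivore	5	1
Stephanorhinus etruscus	herbivore	5	1
Equus altidens	herbivore	3b	1
Equus sp.	herbivore	3b	1
Hippopotamus antiquus	herbivore	5	1
Bison sp.	herbivore	4	1
Hemibos aff. gracilis	herbivore	3b	1
Soergelia minor	herbivore	2	1
Capra alba	herbivore	2	1
Praemegaceros cf. verticornis	herbivore	3b	1
Metacervocerus rhenanus	herbivore	2	1
Cervidae indet.	herbivore	3	0
Herbivore indet. size 0	herbivore	0	0
Herbivore indet. size 1	herbivore	1	0
Herbivore indet. size 2	herbivore	2	0
Herbivore indet. size 3	herbivore	3	0
Herbivore indet. size 3a	herbivore	3a	0
Herbivore indet. size 3b	herbivore	3b	0
Herbivore indet.	herbivore		0
Canis mosbachensis	carnivore	intermediate	1
Canidae indet.	carnivore	intermediate	0
Xenocyon lycaonoides	carnivore	intermediate	1
Vulpes alopecoides	carnivore	small	1
Pachycrocuta brevirostris	carnivore	large	1
Felidae indet.	carnivore	large	0
Lynx sp.	carnivore	small	1
Homotherium latidens	carnivore	large	1
Megantereon cultridens	carnivore	large	1
Panthera cf. gombaszoegensis	carnivore	large	1
Ursus etruscus	carnivore	large	1
Carnivora indet.	carnivore		0
Lagomorpha	other	0	1
Testudines	other	0	1
Aves	other	0	1
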