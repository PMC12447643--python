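family	species	CD300A	CD300C
Cercopithecidae	Papio anubis	1	1
Cercopithecidae	Theropithecus gelada	1	1
Cercopithecidae	Mandrillus leucophaeus	1	1
Cercopithecidae	Cercocebus atys	1	1
Cercopithecidae	Macaca mulatta	1	1
Cercopithecidae	Macaca thibetana thibetana	1	1
Cercopithecidae	Macaca fascicularis	1	1
Cercopithecidae	Macaca nemestrina	1	1
Cercopithecidae	Chlorocebus sabaeus	1	1
Cercopithecidae	Rhinopithecus bieti	1	1*
Cercopithecidae	Rhinopithecus roxellana	1	1
Cercopithecidae	Trachypithecus francoisi	1	1
Cercopithecidae	Piliocolobus tephrosceles	1	1
Cercopithecidae	Colobus angolensis palliatus	1	1
Hominidae	Pan paniscus	1	1
Hominidae	Pan troglodytes	1	1*
Hominidae	Homo sapiens	1	1
Hominidae	Gorilla gorilla gorila	1	1*
Hominidae	Pongo abelii	1	1
Hominidae	Pongo pygmaeus	1	1
Hylobatidae	Hylobates Moloch	1	-
Hylobatidae	Nomascus leucogenys	1	-
Hylobatidae	Symphalangus syndactylus	1	-
Cebidae	Callithrix jacchus	1	1
Cebidae	Aotus nancymaae	1	1
Cebidae	Cebus imitator	1	1
Cebidae	Saimiri boliviensis boliviensis	1	1
Cebidae	Sapajus apella	1	1
Lemuridae	Lemur catta	1	-
Cheirogaleidae	Microcebus murinus	1	1
Indriidae	Propithecus coquereli	1	1
Lorisidae	Nycticebus coucang	1	1
Galagidae	Otolemur garnettii	1	1
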