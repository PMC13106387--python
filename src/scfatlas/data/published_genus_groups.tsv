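# Verbatim transcription of the published delineation of nominal multi-species
# genera of gut Clostridia into groups by minAAI/minPOCP thresholds (65%/50%):
# A = both met, B = AAI only, C = POCP only, D = neither.
# "Pseudoflavonifactor" is transcribed as printed in the table; elsewhere the
# same taxon appears as "Pseudoflavonifractor" (spelling variant preserved).
genus	group
Agathobacter	A
Alectryocaccomicrobium	A
Anaerobutyricum	A
Anaerostipes	A
Anaerotignum	A
Baileyella	A
Borkfalkia	A
Christensenella	A
Clostridioides	A
Clostridium E	A
Clostridium F	A
Clostridium G	A
Coprococcus	A
Coprococcus A	A
Diplocloster	A
Dorea A	A
Egerieicola	A
Eubacterium	A
Eubacterium I	A
Evtepia	A
Extibacter	A
Faecalibacterium	A
Fenollaria	A
Fimimonas	A
Finegoldia	A
Gallimonas	A
Gemmiger	A
Hungatella	A
Intestinimonas	A
Kallipyga	A
Lachnoanaerobaculum	A
Lachnoclostridium B	A
Lachnospira	A
Lentihominibacter	A
Murdochiella	A
Muricomes	A
Negativibacillus	A
Oliverpabstia	A
Paraclostridium	A
Parvimonas	A
Peptostreptococcus	A
Pseudoflavonifactor	A
Roseburia	A
Ruminococcus E	A
Scatavimonas	A
Scatomorpha	A
Sellimonas	A
Stomatobaculum	A
Terrisporobacter	A
Vescimonas	A
Zhenpiania	A
Acutalibacter	B
Agathobaculum	B
Anaerotruncus	B
Bariatricus	B
Blautia	B
Clostridium Q	B
Dysosmobacter	B
Eisenbergiella	B
Faecalimonas	B
Fournierella	B
Limiplasma	B
Mediterraneibacter	B
Anaerococcus	C
Butyribacter	C
Eubacterium R	C
Ezakiella	C
Massilioclostridium	C
Peptoniphilus A	C
Blautia A	D
Clostridium	D
Clostridium J	D
Enterocloster	D
Lachnoclostridium A	D
Marvinbryantia	D
Ruthenibacterium	D
Sarcina	D
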