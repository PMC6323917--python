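species_code	names
hsa	Homo sapiens|H. sapiens|human|humans|patient|patients
mmu	Mus musculus|M. musculus|mouse|mice|murine
rno	Rattus norvegicus|R. norvegicus|rat|rats
dme	Drosophila melanogaster|D. melanogaster|Drosophila|fruit fly|flies
cel	Caenorhabditis elegans|C. elegans|nematode|worm|worms
dre	Danio rerio|D. rerio|zebrafish
ath	Arabidopsis thaliana|A. thaliana|Arabidopsis
bta	Bos taurus|B. taurus|bovine|cattle|cow
gga	Gallus gallus|G. gallus|chicken|chick
ssc	Sus scrofa|S. scrofa|pig|porcine|swine
osa	Oryza sativa|O. sativa|rice
zma	Zea mays|Z. mays|maize
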