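# substring	broad	specific — first match wins, case-insensitive
dna polymerase	replication	dna_polymerase
rna polymerase	replication	rna_polymerase
dna primase	replication	dna_primase
helicase	replication	helicase
dna ligase	replication	dna_ligase
exonuclease	replication	exonuclease
endonuclease	replication	endonuclease
ribonucleotide reductase	replication	ribonucleotide_reductase
thymidylate synthase	replication	thymidylate_synthase
nucleotide metabolism	replication	nucleotide_metabolism
single-stranded dna binding	replication	ssb
terminase	structural	terminase
portal	structural	portal
capsid	structural	capsid
tail fiber	structural	tail_fiber
tail fibre	structural	tail_fiber
baseplate	structural	baseplate
tail tube	structural	tail_tube
tail sheath	structural	tail_sheath
tail	structural	tail
head	structural	head
neck	structural	neck
collar	structural	collar
scaffolding protein	structural	scaffolding
prohead	structural	prohead
photosystem	metabolism	photosystem
oxygenase	metabolism	oxygenase
thioredoxin	metabolism	thioredoxin
ferredoxin	metabolism	ferredoxin
phosphate	metabolism	phosphate_metabolism
cobalamin	metabolism	cobalamin
methyltransferase	metabolism	methyltransferase
glycosyltransferase	metabolism	glycosyltransferase
kinase	metabolism	kinase
transaldolase	metabolism	transaldolase
transcriptional regulator	regulation	transcriptional_regulator
transcription factor	regulation	transcription_factor
sigma factor	regulation	sigma_factor
repressor	regulation	repressor
anti-sigma	regulation	anti_sigma
integrase	replication	integrase
recombinase	replication	recombinase
lysin	structural	lysin
holin	structural	holin
hypothetical	unknown	unknown
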