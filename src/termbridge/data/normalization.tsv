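pattern	canonical_prefix
snomed	snomedct
snomed-ct	snomedct
snomedct	snomedct
snomedct_us	snomedct
sctid	snomedct
sct	snomedct
loinc	loinc
lnc	loinc
rxnorm	rxnorm
rxcui	rxnorm
umls	umls
umls_cui	umls
cui	umls
icd9	icd9cm
icd9cm	icd9cm
icd-9	icd9cm
icd-9-cm	icd9cm
icd10	icd10cm
icd10cm	icd10cm
icd-10	icd10cm
icd-10-cm	icd10cm
icd10who	icd10who
mesh	mesh
msh	mesh
hp	hp
hpo	hp
mondo	mondo
chebi	chebi
ncbitaxon	ncbitaxon
taxonomy	ncbitaxon
ncbi_taxid	ncbitaxon
pr	pr
pro	pr
uberon	uberon
cl	cl
vo	vo
ndfrt	ndfrt
atc	atc
cpt4	cpt4
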