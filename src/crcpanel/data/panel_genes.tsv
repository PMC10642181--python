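symbol	refseq	locus	risk_level	phenotype	lof_mechanism	exon_boundaries
APC	NM_000038.6	5q22.2	high	Familial adenomatous polyposis (FAP)/attenuated FAP; gastric adenocarcinoma and proximal polyposis of the stomach	true
BMPR1A	NM_004329.3	10q23.2	high	Juvenile polyposis syndrome; hereditary mixed polyposis syndrome; pulmonary arterial hypertension	true
EPCAM	NM_002354.3	2p21	high	Lynch syndrome	true
MLH1	NM_000249.4	3p21.3	high	Lynch syndrome; mismatch repair cancer syndrome 1; hereditary breast carcinoma	true	116;207;306;380;453;545;588;677;790;884;1038;1409;1558;1667;1731;1896;2103;2172
MSH2	NM_000251.3	2p22-p21	high	Lynch syndrome; mismatch repair cancer syndrome 1; hereditary breast carcinoma	true
MSH6	NM_000179.3	2p16	high	Lynch syndrome; mismatch repair cancer syndrome 1; hereditary breast carcinoma	true
MUTYH	NM_001128425.2	1p34.1	high	MUTYH-associated polyposis; FAP II	true
PMS2	NM_000535.7	7p22	high	Lynch syndrome; mismatch repair cancer syndrome I; hereditary breast carcinoma	true
POLD1	NM_001256849.1	19q13.33	risk	Polymerase proofreading-associated polyposis	false
POLE	NM_006231.4	12q24.33	risk	Polymerase proofreading-associated polyposis	false
PTEN	NM_000314.8	10q23.31	high	PTEN hamartoma tumor syndrome (Cowden syndrome/Bannayan-Riley-Ruvalcaba syndrome)	true
SMAD4	NM_005359.6	18q21.2	high	Juvenile polyposis syndrome (JPS); JPS/hereditary hemorrhagic telangiectasia syndrome	true
STK11	NM_000455.5	19p13.3	high	Peutz-Jeghers syndrome	true
TP53	NM_000546.5	17p13.1	lower	Li-Fraumeni syndrome	true
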