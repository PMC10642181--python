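patient_id	ihc	variant_gene	variant_cdna	age_band
1	MLH1	MLH1	c.117-1G>A	<40
8	all_positive	POLD1	c.1816C>A	<30
14	all_positive	POLD1	c.1265_1266insG	<30
16	MSH2;MSH6	MSH2	c.1705_1706delGA	<60
17	MSH2	MSH2	c.387_388delTC	<30
19	MLH1	MSH2	c.643C>A	<30
20	MLH1;PMS2	MLH1	c.1731G>A	<50
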