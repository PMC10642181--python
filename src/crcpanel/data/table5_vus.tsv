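gene	transcript	location	maf	function	cdna	protein
MLH1	NM_000249.3	exonic	0.0	Missense	c.1013A>G	p.Asn338Ser
MLH1	NM_000249.4	exonic	NA	Missense	c.1772A>G	p.Asp591Gly
MSH2	NM_000251.3	exonic	NA	Missense	c.508C>G	p.Gln170Glu
MSH2	NM_000251.3	exonic	NA	Missense	c.157G>T	p.Ala53Ser
MSH6	NM_000179.3	exonic	NA	Missense	c.560A>G	p.Lys187Arg
MSH6	NM_000179.3	exonic	NA	Missense	c.2347T>A	p.Cys783Ser
MSH6	NM_000179.3	exonic	NA	Missense	c.3489A>C	p.Glu1163Asp
PMS2	NM_000535.7	exonic	0.0	Missense	c.924G>C	p.Glu308Asp
PMS2	NM_000535.6	exonic	NA	Missense	c.1555T>C	p.Tyr519His
PMS2	NM_000535.7	exonic	0.001	Frameshift	c.2186_2187delTC	p.Leu729GlnfsTer6
APC	NM_000038.6	exonic	NA	Missense	c.5038C>G	p.Gln1680Glu
BMPR1A	NM_004329.3	exonic	NA	Missense	c.185A>G	p.Tyr62Cys
POLE	NM_006231.4	exonic	NA	Missense	c.73G>A	p.Ala25Thr
POLE	NM_006231.4	exonic	NA	Missense	c.4759G>A	p.Val1587Ile
POLE	NM_006231.4	exonic	NA	Missense	c.4144C>T	p.Arg1382Cys
POLE	NM_006231.4	exonic	NA	Missense	c.3901G>A	p.Val1301Met
POLE	NM_006231.4	exonic	NA	Missense	c.1004T>G	p.Phe335Cys
POLE	NM_006231.3	exonic	NA	Missense	c.4124C>T	p.Ala1375Val
POLE	NM_006231.3	exonic	NA	Missense	c.1337G>A	p.Arg446Gln
POLE	NM_006231.4	exonic	NA	Missense	c.3311C>T	p.Thr1104Met
POLE	NM_006231.4	exonic	NA	Missense	c.3970C>T	p.Arg1324Cys
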