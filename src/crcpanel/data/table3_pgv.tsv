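patient_id	gene	cdna	protein	maf	clinvar	acmg	reported_before	family_history	deceased
1	MLH1	c.117-1G>A	p.?	NA	Pathogenic	Pathogenic	No (G>T only)	yes	no
2	MLH1	c.2263A>G	p.Arg755Gly	NA	Pathogenic	Pathogenic	No	no	yes
3	MLH1	c.117-1G>A	p.?	NA	Pathogenic	Pathogenic	No (G>T only)	no	no
4	MLH1	c.793C>T	p.Arg265Cys	NA	Pathogenic	Pathogenic	Yes	no	no
5	BMPR1A	c.834C>A	p.Tyr278Ter	NA	Pathogenic	Pathogenic	No	no	yes
6	BMPR1A	c.717delA	p.Val240LeufsTer21	NA	No entry	Pathogenic	No	no	yes
7	MSH2	c.2377C>T	p.Gln793Ter	NA	Pathogenic/likely pathogenic	Pathogenic	No	no	no
8	POLD1	c.1816C>A	p.Leu606Met	NA	Conflicting interpretation of pathogenicity	Likely pathogenic	Yes (de novo in one African)	no	yes
9	BMPR1A	c.185A>G	p.Tyr62Cys	NA	Uncertain significance	Likely pathogenic	No	no	no
10	PMS2	c.2192_2196delTAACT	p.Leu731CysfsTer3	0.0	Pathogenic	Pathogenic	Yes	no	no
11	BMPR1A	c.717delA	p.Val240LeufsTer21	NA	No entry	Pathogenic	No	no	no
12	MSH2	c.187delG	p.Val63Ter	NA	Pathogenic	Pathogenic	Yes (breast cancer)	yes	no
13	TP53	c.526T>C	p.Cys176Arg	NA	Conflicting interpretation of pathogenicity	Pathogenic	Yes (only somatic)	no	no
14	POLD1	c.1265_1266insG	p.Arg423ProfsTer212	NA	No entry	Pathogenic	No	no	no
15	BMPR1A	c.355C>T	p.Arg119Cys	NA	Conflicting interpretation of pathogenicity	Pathogenic	Yes	no	no
16	MSH2	c.1705_1706delGA	p.Glu569IlefsTer2	NA	Pathogenic	Pathogenic	Yes	no	no
17	MSH2	c.387_388delTC	p.Gln130fs	NA	Pathogenic	Pathogenic	Yes	yes	no
18	PMS2	c.1579_1580delAG	p.Arg527GlyfsTer14	0.0	Pathogenic	Pathogenic	Yes (breast/ovarian cancer)	no	no
19	MSH2	c.643C>A	p.Gln215Lys	NA	No entry	Likely pathogenic	No (C>T only)	no	no
20	MLH1	c.1731G>A	p.Ser577=	NA	Pathogenic	Pathogenic	Yes	no	yes
21	MSH2	c.1923T>A	p.Cys641Ter	NA	No entry	Pathogenic	No	no	no
21	PMS2	c.2192_2196delTAACT	p.Leu731CysfsTer3	0.0	Pathogenic	Pathogenic	Yes	no	no
22	PMS2	c.2192_2196delTAACT	p.Leu731CysfsTer3	0.0	Pathogenic	Pathogenic	Yes	no	no
23	MSH2	c.187_188insG	p.Val63fs	NA	Pathogenic	Pathogenic	Yes	no	no
24	MUTYH	c.1476+2C>T	p.?	0.002	Conflicting interpretations of pathogenicity	Likely pathogenic	Yes	no	no
25	MSH2	c.1569delT	p.Arg524ValfsTer2	NA	Pathogenic	Pathogenic	Yes	no	no
26	TP53	c.742C>T	p.Arg248Trp	NA	Pathogenic	Pathogenic	Yes	no	no
27	APC	c.2868C>A	p.Tyr956Ter	NA	No entry	Likely pathogenic	No (C>G only)	no	no
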