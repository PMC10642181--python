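variable	category	all	positive	negative	p_value	method
total	n	107	27	80
diagnosis_age	mean_sd	35.64 (8.71)	35.33 (9.24)	35.76 (8.58)
diagnosis_age	median	37	35	37	0.630	wilcoxon_rank_sum
diagnosis_age	range	26 to 58	26 to 58	18 to 58
categorical_age	<50	104	25	79	0.156	fisher_exact
categorical_age	>=50	3	2	1
gender	male	54	15	39	0.697	chi_squared_yates
gender	female	53	12	41
localization	colon	79	18	61	0.069	fisher_exact
localization	rectum	25	7	18
localization	both	2	2	0
localization	not_applicable	1	0	1
sidedness	right	47	12	35	0.144	fisher_exact
sidedness	left	47	10	37
sidedness	both	7	4	3
sidedness	not_applicable	6	1	5
ihc	loss	14	5	9
ihc	normal	9	3	6
ihc	not_applicable	84	19	66
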