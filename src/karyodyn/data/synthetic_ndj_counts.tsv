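assay_id	block	phenotype_class	count
ndj_survey	b1	regular_female	16656
ndj_survey	b1	xxy_female	9
ndj_full	b1	regular_female	5391
ndj_full	b1	xxy_female	9
ndj_full	b1	regular_male	5390
ndj_full	b1	xnull_male	59
ndj_sexed	b1	regular_female	5311
ndj_sexed	b1	regular_male	5311
ndj_sexed	b1	maternal_xxy_female	10
ndj_sexed	b1	paternal_xxy_female	8
ndj_sexed	b1	maternal_null_male	22
ndj_sexed	b1	paternal_null_male	2
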