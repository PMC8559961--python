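assay	metric	n_sp	n_ckr	n_both
RNA-seq	differential_expression	1095	456	366
RNA-seq	overexpressed_cyps	22	15	14
RNA-seq	homozygous_snps	60527	34665	14350
Proteomics	differential_expression	286	139	57
Proteomics	overexpressed_cyps	28	16	16
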