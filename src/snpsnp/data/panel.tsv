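# 15-locus SNP-SNP microhaplotype panel: amplicon geometry, per-primer
# allele targets, limits of detection (heterozygous-input ng) and observed
# CE product sizes.
# Allele labels and F1/F2 target assignments are pinned where published
# mixture genotypes constrain them (MH3, MH8, MH9, MH10, MH11, MH12, MH13;
# MH9-F1 targets C, MH9-F2 targets T); the rest are synthetic placeholders.
# Observed sizes for MH1-F2, MH12-F1, MH13-F2 and MH14-F1 (primers never
# informative in the reference cohort) are synthetic fills equal to the
# locus partner's observed size.
locus_id	snp1_alleles	snp2_alleles	arms_amplicon_bp	sbe_amplicon_bp	f1_target	f1_lod_ng	f1_observed_bp	f2_target	f2_lod_ng	f2_observed_bp
MH1	C/T	A/G	134	26	C	0.025	34	T	0.025	34
MH2	A/G	C/T	108	32	A	0.05	41	G	0.025	41
MH3	C/T	C/T	121	36	C	0.025	42	T	0.025	41
MH4	G/A	T/C	101	43	G	0.025	46	A	0.05	46
MH5	A/C	G/T	60	52	A	0.025	56	C	0.025	56
MH6	T/G	A/C	114	61	T	0.025	64	G	0.025	64
MH7	C/G	A/T	90	65	C	0.05	67	G	0.025	67
MH8	A/C	A/G	126	71	A	0.025	77	C	0.025	77
MH9	C/T	A/G	150	27	C	0.025	35	T	0.05	33
MH10	G/C	T/C	106	31	G	0.025	39	C	0.05	38
MH11	C/T	A/G	69	35	C	0.025	43	T	0.05	42
MH12	T/C	G/A	141	39	T	0.025	44	C	0.05	44
MH13	C/T	G/A	95	43	C	0.05	48	T	0.05	48
MH14	A/T	G/C	79	58	A	0.025	61	T	0.05	61
MH15	G/T	C/A	113	63	G	0.025	68	T	0.025	68
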