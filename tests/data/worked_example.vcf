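##fileformat=VCFv4.2
##contig=<ID=ref,length=14>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	HG00096	HG00101	HG00103
ref	2	.	A	G	.	PASS	.	GT	0|0	0|1	0|1
ref	2	.	AATT	A	.	PASS	.	GT	1|0	0|0	0|0
ref	6	.	T	TACG	.	PASS	.	GT	0|0	0|0	0|1
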