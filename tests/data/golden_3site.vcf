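##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Float,Description="Mean sample depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	a	b	c	d
chr1	11	.	A	T	30	.	DP=12.5	GT	0/0	0/1	1/1	./.
chr1	25	.	G	C	55.5	.	DP=40	GT	1/1	1/1	0/0	0/1
chr2	7	.	T	A	11	.	DP=99	GT	0/0	0/0	0/1	0/1
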