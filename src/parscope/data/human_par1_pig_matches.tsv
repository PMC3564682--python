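# Human PAR1 genes and the location of each one's closest match in the pig
# genome (Sscrofa10.2). Multi-chromosome matches list the closest first,
# separated by ';'. The par_region flag marks matches landing in
# pseudoautosomal sequence without a gene-level coordinate.
gene_id	symbol	chrom	position	flags
ENSG00000182378	PLCXD1	NO_MATCH
ENSG00000178605	GTPBP6	NO_MATCH
ENSG00000167393	PPP2R3B	SSC13
ENSG00000185960	SHOX	SSCX		par_region
ENSG00000205755	CRLF2	NO_MATCH
ENSG00000198223	CSF2RA	NO_MATCH
ENSG00000185291	IL3RA	NO_MATCH
ENSG00000169100	SLC25A6	SSCX	96700000
ENSG00000169093	ASMTL	NO_MATCH
ENSG00000182162	P2RY8	SSCX		par_region,no_gene
ENSG00000197976	AKAP17A	SSC1;SSC16
ENSG00000196433	ASMT	NO_MATCH
ENSG00000169084	DHRSX	SSCX;SSC5	89000000
ENSG00000214717	ZBED1	SSC9;SSC1;SSC8		no_gene
ENSG00000002586	CD99	NO_MATCH
ENSG00000124343	XG	NO_MATCH
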