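l1_chrom	l1_start	l1_end	l1_id	gene_name	gene_alteration	sample_id
chr11	14799221	14805319	L1PA5:L1:LINE	PDE3B	Upregulated	SRR9292614
chr1	68553278	68559388	L1PA6:L1:LINE	WLS	Upregulated	SRR9292620
chr11	14799221	14805319	L1PA5:L1:LINE	PDE3B	Upregulated	SRR9292620
chr11	132190054	132196077	L1PA4:L1:LINE	NTM	Upregulated	SRR9292620
chr5	139895099	139900527	L1PA3:L1:LINE	ANKHD1-EIF4EBP3	Upregulated	SRR9292620
chr1	220814954	220821404	L1PA10:L1:LINE	MARK1	Downregulated	SRR9292620
chr10	49580263	49585413	L1PA7:L1:LINE	MAPK8	Downregulated	SRR9292620
chr11	132626675	132633167	L1PA7:L1:LINE	OPCML	Downregulated	SRR9292620
chr18	3695243	3700586	L1PA7:L1:LINE	DLGAP1	Downregulated	SRR9292620
chr19	40543822	40549961	L1PA4:L1:LINE	ZNF780B	Downregulated	SRR9292620
chr5	139895099	139900527	L1PA3:L1:LINE	ANKHD1-EIF4EBP3	Upregulated	SRR9292621
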