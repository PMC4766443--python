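region	chrom	pos	site	pop	n	derived	daf	fst	fst_maf	ipi_a	ipi_d	dind_raw	dind_sentinel	dind_ok	fst_rank	dind	dind_rank	joint_flag	ld_cluster	ld_partners	final_flag
sweep_gene	chrA	4400	7	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	4700	8	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	5000	9	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	5300	10	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	5600	11	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
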