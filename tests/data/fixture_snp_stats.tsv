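region	chrom	pos	site	pop	n	derived	daf	fst	fst_maf	ipi_a	ipi_d	dind_raw	dind_sentinel	dind_ok	fst_rank	dind	dind_rank	joint_flag	ld_cluster	ld_partners	final_flag
sweep_gene	chrA	300	0	pop1	12	12	1	1	0.5				False	False	1			False		0	False
sweep_gene	chrA	500	1	pop1	12	1	0.08333333333	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	1200	2	pop1	12	1	0.08333333333	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	1900	3	pop1	12	1	0.08333333333	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	2600	4	pop1	12	2	0.1666666667	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	3300	5	pop1	12	2	0.1666666667	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	4000	6	pop1	12	2	0.1666666667	0.1515151515	0.3333333333	1.6	4	0.4	False	True	0.75	0.4	0	False		0	False
sweep_gene	chrA	4400	7	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	4700	8	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	5000	9	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	5300	10	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	5600	11	pop1	12	9	0.75	0.7272727273	0.375	4	0		True	True	1	20.97674419	1	True	sweep_gene:pop1:c0	4	True
sweep_gene	chrA	6000	12	pop1	12	1	0.08333333333	0.2878787879	0.2916666667	2.690909091	0		True	True	0.5	20	0.1793640516	False		0	False
sweep_gene	chrA	6700	13	pop1	12	1	0.08333333333	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	7400	14	pop1	12	1	0.08333333333	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	8100	15	pop1	12	2	0.1666666667	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	8800	16	pop1	12	2	0.1666666667	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	9500	17	pop1	12	2	0.1666666667	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	300	0	pop2	12	0	0	1	0.5				False	False	1			False		0	False
sweep_gene	chrA	500	1	pop2	12	6	0.5	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	1200	2	pop2	12	6	0.5	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	1900	3	pop2	12	6	0.5	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	2600	4	pop2	12	6	0.5	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	3300	5	pop2	12	6	0.5	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	4000	6	pop2	12	6	0.5	0.1515151515	0.3333333333	4.266666667	4.266666667	1	False	True	0.75	1	0.1666666667	False		0	False
sweep_gene	chrA	4400	7	pop2	12	0	0	0.7272727273	0.375				False	False	1			False		0	False
sweep_gene	chrA	4700	8	pop2	12	0	0	0.7272727273	0.375				False	False	1			False		0	False
sweep_gene	chrA	5000	9	pop2	12	0	0	0.7272727273	0.375				False	False	1			False		0	False
sweep_gene	chrA	5300	10	pop2	12	0	0	0.7272727273	0.375				False	False	1			False		0	False
sweep_gene	chrA	5600	11	pop2	12	0	0	0.7272727273	0.375				False	False	1			False		0	False
sweep_gene	chrA	6000	12	pop2	12	6	0.5	0.2878787879	0.2916666667	4.266666667	4.266666667	1	False	True	0.5	1	0.1666666667	False		0	False
sweep_gene	chrA	6700	13	pop2	12	6	0.5	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	7400	14	pop2	12	6	0.5	0.2878787879	0.2916666667				False	False	0.5			False		0	False
sweep_gene	chrA	8100	15	pop2	12	6	0.5	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	8800	16	pop2	12	6	0.5	0.1515151515	0.3333333333				False	False	0.75			False		0	False
sweep_gene	chrA	9500	17	pop2	12	6	0.5	0.1515151515	0.3333333333				False	False	0.75			False		0	False
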