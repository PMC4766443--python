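region	chrom	start	end	pop	S	dh	available	below_threshold
sweep_gene	chrA	0	5000	pop1	9	-0.6586535544	True	True
sweep_gene	chrA	500	5500	pop1	9	-1.160484834	True	True
sweep_gene	chrA	1000	6000	pop1	11	-1.281576267	True	True
sweep_gene	chrA	1500	6500	pop1	10	-1.456367349	True	True
sweep_gene	chrA	2000	7000	pop1	10	-1.456367349	True	True
sweep_gene	chrA	2500	7500	pop1	11	-1.281576267	True	True
sweep_gene	chrA	3000	8000	pop1	10	-1.499625785	True	True
sweep_gene	chrA	3500	8500	pop1	10	-1.499625785	True	True
sweep_gene	chrA	4000	9000	pop1	10	-1.499625785	True	True
sweep_gene	chrA	4500	9500	pop1	10	-0.9949440304	True	True
sweep_gene	chrA	5000	10000	pop1	8	-0.257965066	True	False
sweep_gene	chrA	0	5000	pop2	6	0	True	False
sweep_gene	chrA	500	5500	pop2	5	0	True	False
sweep_gene	chrA	1000	6000	pop2	6	0	True	False
sweep_gene	chrA	1500	6500	pop2	5	0	True	False
sweep_gene	chrA	2000	7000	pop2	5	0	True	False
sweep_gene	chrA	2500	7500	pop2	6	0	True	False
sweep_gene	chrA	3000	8000	pop2	5	0	True	False
sweep_gene	chrA	3500	8500	pop2	5	0	True	False
sweep_gene	chrA	4000	9000	pop2	5	0	True	False
sweep_gene	chrA	4500	9500	pop2	6	0	True	False
sweep_gene	chrA	5000	10000	pop2	6	0	True	False
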