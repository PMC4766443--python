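pos	ancestral	derived	pooled_daf	all_ancestral	mhs_flag	status_Altai	status_Denisova
4400	A	G	0.375	True	False	ancestral_homozygous	ancestral_homozygous
4700	A	G	0.375	True	False	ancestral_homozygous	ancestral_homozygous
5000	A	G	0.375	True	False	ancestral_homozygous	ancestral_homozygous
5300	A	G	0.375	True	False	ancestral_homozygous	ancestral_homozygous
5600	A	G	0.375	True	False	ancestral_homozygous	ancestral_homozygous
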