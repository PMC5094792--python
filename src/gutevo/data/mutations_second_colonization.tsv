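clone_id	population_id	host_id	position	locus	category	region	allele
clone16	2.1	M2.1	2825670	srlR	SNP_nonsense	coding	C->T (Q104*)
clone16	2.1	M2.1	4344556	dcuB	IS_insertion	intergenic	IS5 upstream (-112)
clone17	2.2	M2.2	4638820	arcA	IS_insertion	intergenic	IS5 regulatory (-68)
clone17	2.2	M2.2	320450	ykgB/ykgC	large_deletion	structural	del 8.2 kb
clone18	2.3	M2.3	945120	focA	IS_insertion	intergenic	IS1 upstream (-90)
clone18	2.3	M2.3	2825944	srlR	small_indel	coding	+G (274/777 nt)
clone19	2.4	M2.4	4344601	dcuB	IS_insertion	intergenic	IS2 upstream (-67)
clone19	2.4	M2.4	4608216	yjjP	IS_insertion	intergenic	IS186 promoter (-41)
clone20	2.5	M2.5	4590000	radA-dup	large_duplication	structural	dup 157 kb incl arcA
clone20	2.5	M2.5	3650321	insQ	IS_insertion	coding	IS5 in insQ (412/1216 nt)
clone21	2.6	M2.6	4638795	arcA	IS_insertion	intergenic	IS1 regulatory (-93)
clone21	2.6	M2.6	1299850	oppB	IS_insertion	coding	IS2 in oppB (210/921 nt)
clone22	2.7	M2.7	4344590	dcuB	small_indel	intergenic	+AT upstream (-78)
clone22	2.7	M2.7	945162	focA	small_indel	intergenic	delta 1 bp (-48)
clone22	2.7	M2.7	4434860	pphB	SNP_nonsynonymous	coding	G->A (R121H)
clone23	2.8	M2.8	2825801	srlR	SNP_nonsynonymous	coding	A->C (N131T)
clone23	2.8	M2.8	4590000	radA-dup	large_duplication	structural	dup 62 kb incl arcA
clone24	2.9	M2.9	945162	focA	small_indel	intergenic	+C upstream (-48)
clone24	2.9	M2.9	2992410	ygeF	IS_insertion	coding	IS186 in ygeF (101/690 nt)
clone25	2.10	M2.10	4590000	radA-dup	large_duplication	structural	dup 34 kb incl arcA
clone25	2.10	M2.10	4608180	yjjP	small_indel	intergenic	delta 2 bp promoter (-77)
clone26	2.11	M2.11	4638808	arcA	IS_insertion	intergenic	IS5 regulatory (-80)
clone26	2.11	M2.11	2825944	srlR	small_indel	coding	+G (274/777 nt)
clone27	2.12	M2.12	4344590	dcuB	small_indel	intergenic	+A upstream (-78)
clone27	2.12	M2.12	1299944	oppB	IS_insertion	coding	IS5 in oppB (304/921 nt)
clone28	2.13	M2.13	2825712	srlR	SNP_nonsynonymous	coding	T->G (L56R)
clone28	2.13	M2.13	389120	yaiT/yaiV	large_deletion	structural	del 12.6 kb
clone29	2.14	M2.14	4638832	arcA	IS_insertion	intergenic	IS2 regulatory (-56)
clone29	2.14	M2.14	4246110	malE	IS_insertion	coding	IS1 in malE (508/1191 nt)
clone30	2.15	M2.15	2764991	yfjL	IS_insertion	coding	IS5 in yfjL (233/1020 nt)
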