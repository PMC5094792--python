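clone_id	population_id	host_id	position	locus	category	region	allele
clone1	1.1	M1.1	1905410	yecT	IS_insertion	coding	IS5 in yecT (88/549 nt)
clone1	1.1	M1.1	2530115	iscR	SNP_nonsynonymous	coding	C->A (A51E)
clone2	1.2	M1.2	3815220	rffA	small_indel	coding	delta 1 bp (610/1131 nt)
clone2	1.2	M1.2	4120990	frwC	IS_insertion	coding	IS2 in frwC (901/1080 nt)
clone3	1.3	M1.3	2170560	yegQ	SNP_nonsynonymous	coding	G->T (D230Y)
clone3	1.3	M1.3	1461200	ydbD	IS_insertion	intergenic	IS1 upstream (-102)
clone4	1.4	M1.4	3361870	yhcC	small_indel	coding	+A (415/948 nt)
clone4	1.4	M1.4	990450	torS	SNP_nonsynonymous	coding	A->G (I600V)
clone5	1.5	M1.5	2825944	srlR	small_indel	coding	+G (274/777 nt)
clone5	1.5	M1.5	1180330	ycdT	IS_insertion	coding	IS5 in ycdT (360/1367 nt)
clone6	1.6	M1.6	4344612	dcuB	IS_insertion	intergenic	IS5 upstream (-56)
clone6	1.6	M1.6	545900	ylbE	small_indel	coding	delta 2 bp (122/450 nt)
clone7	1.7	M1.7	2899540	ygfZ	IS_insertion	intergenic	IS186 promoter (-64)
clone7	1.7	M1.7	3470110	rpoD	SNP_nonsynonymous	coding	C->T (P504S)
clone8	1.8	M1.8	1616800	ydgH	large_deletion	structural	del 5.4 kb
clone8	1.8	M1.8	2240170	yejG	IS_insertion	coding	IS1 in yejG (90/345 nt)
clone9	1.9	M1.9	2825690	srlR	SNP_nonsense	coding	G->A (W82*)
clone9	1.9	M1.9	1720450	ydhB	IS_insertion	intergenic	IS5 upstream (-71)
clone10	1.10	M1.10	4035780	zraP	small_indel	intergenic	+T promoter (-39)
clone10	1.10	M1.10	610250	ahpF	SNP_synonymous	coding	C->T (L210L)
clone11	1.11	M1.11	2465110	eutB	IS_insertion	coding	IS2 in eutB (700/1362 nt)
clone11	1.11	M1.11	3120900	ygiS	small_indel	coding	delta 1 bp (411/1008 nt)
clone12	1.12	M1.12	4590000	radA-dup	large_duplication	structural	dup 44 kb incl arcA
clone12	1.12	M1.12	1245080	ymgA	IS_insertion	intergenic	IS5 upstream (-84)
clone13	1.13	M1.13	3980115	hslU	SNP_nonsynonymous	coding	T->C (F90L)
clone13	1.13	M1.13	870430	ybiO	IS_insertion	coding	IS186 in ybiO (233/2226 nt)
clone14	1.14	M1.14	2015660	wbbK	IS_insertion	intergenic	IS1 upstream (-120)
clone14	1.14	M1.14	1350240	ycjX	small_indel	coding	+C (810/1398 nt)
clone1	1.1	M1.1	3692480	rbsR	small_indel	coding	+A (505/993 nt)
clone4	1.4	M1.4	2601330	clpB	SNP_synonymous	coding	G->A (K402K)
clone8	1.8	M1.8	4505190	ytfJ	IS_insertion	intergenic	IS5 upstream (-66)
clone13	1.13	M1.13	1130990	flgE	small_indel	coding	delta 1 bp (380/1206 nt)
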