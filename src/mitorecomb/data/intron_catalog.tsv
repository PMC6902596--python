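# Reference catalog of liverwort mitochondrial introns, keyed by host
# gene and nucleotide insertion position in the gene's coding sequence.
# Group assignment (I/II) follows the standard nomenclature, not RNA
# structure inference. Entries for atp1, cob 372/693, cox1 511-1305,
# cox2, nad1-nad9, rps and trnS are SYNTHETIC placeholder positions used
# to exercise catalog matching in simulated genomes; only cob824, cox1
# 44/178/375, nad4L 100/283, rrn18 1065 and rrn26 827/2352 are
# literature-documented insertion sites.
gene	insertion_pos	group
atp1	361	g2
cob	372	g1
cob	693	g2
cob	824	g2
cox1	44	g2
cox1	178	g2
cox1	375	g1
cox1	511	g1
cox1	624	g1
cox1	732	g1
cox1	876	g2
cox1	1064	g2
cox1	1305	g1
cox2	97	g2
cox2	281	g1
cox2	373	g1
cox2	564	g2
nad1	287	g2
nad1	477	g2
nad1	728	g2
nad2	156	g2
nad2	542	g2
nad2	709	g2
nad3	52	g2
nad4	461	g1
nad4	976	g2
nad4L	100	g2
nad4L	283	g2
nad5	230	g1
nad5	881	g2
nad5	1242	g2
nad7	336	g2
nad7	917	g2
nad9	246	g2
rps3	74	g2
rps14	114	g2
rrn18	1065	g2
rrn26	827	g2
rrn26	2352	g1
trnS	32	g1
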