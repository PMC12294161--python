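region	chrom	start	end	gene_id	delta_a	delta_b	delta_ab
promoter	19	13841885	13841989	CCDC130	14.2	11.8	2.4
promoter	14	77495636	77495807	IRF2BPL	-12.2	-10.2	-2.0
promoter	17	33776642	33776791	SLFN13	18.1	11.7	6.4
promoter	16	84076941	84077080	SLC38A8	12.7	13.0	-0.3
promoter	19	36249868	36250044	HSPB6	11.1	10.3	0.8
promoter	16	4527540	4527641	NMRAL1	-32.0	-12.5	-19.5
promoter	14	55587537	55587752	LGALS3	28.5	14.8	13.7
promoter	20	57581333	57581441	CTSZ	21.2	18.2	2.8
promoter	20	35170171	35170286	MYL9	13.2	11.6	1.6
promoter	12	2027243	2027352	CACNA2D4	17.7	17.6	0.1
promoter	6	36969405	36969621	FGD2	21.7	-11.1	32.8
promoter	6	31939186	31939321	DOM3Z	21.4	15.6	5.8
exon	1	245851466	245851609	KIF26B	-19.0	-18.7	-0.3
exon	8	61778005	61778136	CHD7	-29.2	-14.5	-14.7
exon	1	226821736	226821914	ITPKB	-12.1	-13.1	1.0
exon	17	40463432	40463555	STAT5A	16.2	11.4	4.8
exon	20	3732943	3733092	HSPA12B	18.3	-15.6	33.9
exon	19	1047184	1047347	ABCA7	24.6	11.8	12.8
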