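chrom	start	end	location	gene_id	delta_a	delta_b	delta_ab
18	34854648	34854693	intron	CELF4	-13.9	15.1	-29.0
1	90074598	90074699	intergenic		-36.4	-15.7	-20.7
16	4527540	4527641	promoter	NMRAL1	-32.0	-12.5	-19.5
5	39185995	39186145	intron	FYB	-33.3	-14.5	-18.8
2	240241154	240241261	intergenic		13.4	32.2	-18.8
7	158766236	158766379	intergenic		18.4	35.4	-17.0
8	61778005	61778136	exon	CHD7	-29.2	-14.5	-14.7
17	76129099	76129221	intron	TMC8	-24.7	-13.3	-11.4
6	30854000	30854160	intron	DDR1	-22.4	-11.0	-11.4
17	75429645	75429795	intergenic		-21.9	-10.6	-11.3
1	59090260	59090360	intergenic		12.4	22.8	-10.6
2	121955379	121955533	intergenic		22.3	12.2	10.1
16	3137553	3137716	intergenic	ZNF205	26.1	14.7	11.4
19	1047184	1047347	exon	ABCA7	24.6	11.8	12.8
7	158250978	158251159	intergenic		28.1	15.3	12.8
14	55587537	55587752	promoter	LGALS3	28.5	14.8	13.7
15	75336231	75336352	intron	PPCDC	26.5	10.8	15.7
8	58055165	58055309	intergenic		27.6	11.7	15.9
21	46714776	46714890	intergenic		31.5	13.8	17.7
8	58055310	58055463	intergenic		34.2	15.7	18.5
1	19110747	19110909	intergenic		-16.7	-35.4	18.7
17	76661321	76661487	intergenic		11.8	-11.3	23.1
10	118025165	118025303	intergenic		13.1	-13.1	26.2
6	36969405	36969621	promoter	FGD2	21.7	-11.1	32.8
20	3732943	3733092	exon	HSPA12B	18.3	-15.6	33.9
3	126945870	126946029	intergenic		11.4	-25.9	37.3
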