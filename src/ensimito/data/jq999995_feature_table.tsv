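# Published annotation of the Tarragoilus diuturnus mitochondrial genome
# (GenBank JQ999995), transcribed from the deposited feature coordinates.
# Columns: size and spacer are derived from start/end on the 16144 bp circle.
#genome_length=16144
gene	klass	strand	start	end	size	anticodon	init_codon	term_codon	spacer
trnI	tRNA	J	1	67	67	GAT	.	.	3
trnQ	tRNA	N	71	139	69	TTG	.	.	-1
trnM	tRNA	J	139	207	69	CAT	.	.	0
nad2	PCG	J	208	1234	1027	.	ATA	T	0
trnW	tRNA	J	1235	1300	66	TCA	.	.	-8
trnC	tRNA	N	1293	1358	66	GCA	.	.	5
trnY	tRNA	N	1364	1428	65	GTA	.	.	-8
cox1	PCG	J	1421	2960	1540	.	ATC	T	0
trnL_UUR	tRNA	J	2961	3028	68	TAA	.	.	0
cox2	PCG	J	3029	3719	691	.	ATA	T	0
trnK	tRNA	J	3720	3789	70	CTT	.	.	0
trnD	tRNA	J	3790	3855	66	GTC	.	.	0
atp8	PCG	J	3856	4014	159	.	GTG	TAG	-7
atp6	PCG	J	4008	4685	678	.	ATG	TAA	-1
cox3	PCG	J	4685	5473	789	.	ATG	TAA	4
trnG	tRNA	J	5478	5544	67	TCC	.	.	0
nad3	PCG	J	5545	5898	354	.	ATA	TAA	6
trnA	tRNA	J	5905	5967	63	TGC	.	.	3
trnR	tRNA	J	5971	6035	65	TCG	.	.	25
trnN	tRNA	J	6061	6126	66	GTT	.	.	0
trnS_AGN	tRNA	J	6127	6193	67	GCT	.	.	3
trnE	tRNA	J	6197	6261	65	TTC	.	.	-2
trnF	tRNA	N	6260	6327	68	GAA	.	.	0
nad5	PCG	N	6328	8062	1735	.	ATG	T	0
trnH	tRNA	N	8063	8125	63	GTG	.	.	0
nad4	PCG	N	8126	9464	1339	.	ATG	T	-7
nad4L	PCG	N	9458	9754	297	.	ATG	TAA	2
trnT	tRNA	J	9757	9819	63	TGT	.	.	-1
trnP	tRNA	N	9819	9888	70	TGG	.	.	1
nad6	PCG	J	9890	10417	528	.	ATT	TAA	-1
cytb	PCG	J	10417	11551	1135	.	ATG	T	0
trnS_UCN	tRNA	J	11552	11619	68	TGA	.	.	16
nad1	PCG	N	11636	12586	951	.	ATA	TAA	0
trnL_CUN	tRNA	N	12587	12650	64	TAG	.	.	0
rrnL	rRNA	N	12651	13990	1340	.	.	.	0
trnV	tRNA	N	13991	14060	70	TAC	.	.	0
rrnS	rRNA	N	14061	14843	783	.	.	.	0
control_region	control	J	14844	16144	1301	.	.	.	0
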