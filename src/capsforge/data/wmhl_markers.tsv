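# Published WMHL (watermelon high-lycopene) CAPS marker panel: 19 SNPs on protein-coding
# genes that discriminate red-flesh (lycopene-high, LH) from non-red (lycopene-low, LL)
# inbred watermelon lines, each converted to a CAPS assay.
# product_size_*: predicted amplicon fragment sizes in bp, comma-separated; a single
# number means the allele is not cut by the enzyme.
marker	chrom	position	ref	lh_allele	ll_allele	accession	gene_name	location	enzyme	product_size_lh	product_size_ll
WMHL1	Chr2	24493443	G	G	A	Cla020048	Myosin 1	intron	HindIII	94	27,67
WMHL2	Chr2	24518665	T	T	C	Cla020046	F-box/LRR-repeat protein 20	exon	AccI	59,89	148
WMHL3	Chr2	24751497	A	A	G	Cla020024	Pre-mRNA-splicing factor RBM22	exon	XhoI	123	20,98
WMHL4	Chr2	24830110	T	T	C	Cla020015	Signal recognition particle protein	intron	SacI	81	50,31
WMHL5	Chr2	24843410	A	A	G	Cla020013	Vacuolar protein sorting-associated protein 27	exon	ApeKI	155	54,101
WMHL6	Chr2	24877311	T	T	C	Cla020012	Cyclic nucleotide gated channel 9	intron	XbaI	203	72,130
WMHL7	Chr2	24886838	C	C	T	Cla020011	Leucine aminopeptidase 1	intron	SalI	94,154	249
WMHL8	Chr4	8923655	A	A	G	Cla005012	Kinesin-like protein	intron	BsrI	468	171,296
WMHL9	Chr4	9807020	C	C	T	Cla006835	Unknown Protein	exon	AvaI	90	33,57
WMHL10	Chr4	9807385	A	A	G	Cla006835	Unknown Protein	intron	SalI	196	54,141
WMHL11	Chr4	10209760	T	T	C	Cla006847	Unknown Protein (AHRD V1)	intron	BbsI	45,80	126
WMHL12	Chr4	10826029	G	G	A	Cla006858	Transcription initiation factor IIB-2	exon	BsrI	53,182	236
WMHL13	Chr4	10838374	A	A	G	Cla006859	Pentatricopeptide repeat-containing protein	exon	BsrI	484	183,301
WMHL14	Chr5	20321987	A	A	G	Cla000884	mRNA clone RTFL01-05-M08	intron	EcoNI	160	59,101
WMHL15	Chr5	21363473	A	A	G	Cla004209	Trafficking protein particle complex subunit 3	intron	Bsu36I	146	35,101
WMHL16	Chr9	22158134	G	G	A	Cla012979	Cleavage and polyadenylation specificity factor subunit 3	intron	PstI	134	26,99
WMHL17	Chr9	22239355	C	C	A	Cla012981	Unknown Protein	exon	PstI	54,95	149
WMHL18	Chr10	26477503	T	C	T	Cla017825	Zinc finger protein	exon	NruI	50,86	136
WMHL19	Chr10	26681481	C	T	C	Cla017847	Receptor-like kinase	intron	NdeI	119,291	410
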