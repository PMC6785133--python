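# Published validation matrix for the 19 WMHL CAPS markers across 24 inbred watermelon
# lines. Each sample cell is a pair "seq/caps": the whole-genome-resequencing call and
# the CAPS assay call, each written as a single genotype symbol (nucleotide = homozygote,
# two-fold IUPAC code = heterozygote, '-' = no call, e.g. a failed PCR).
# The first 9 sample columns are the red-flesh, lycopene-high lines; the remaining 15
# are the non-red, lycopene-low lines. match_rate is the published concordance.
marker	chrom	position	ref	801	802	803	812	829	830	832	917	45	816	819	833	834	835	837	838	3	820	840	842	843	919	1	29	match_rate
WMHL1	Chr2	24493443	G	G/G	G/G	G/G	G/-	G/G	G/G	G/G	G/G	G/G	A/A	G/G	A/A	R/R	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	G/G	1
WMHL2	Chr2	24518665	T	T/T	T/T	T/T	T/-	T/T	T/T	T/T	T/T	T/T	C/C	T/T	C/C	Y/C	C/T	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	T/T	0.92
WMHL3	Chr2	24751497	A	A/A	A/A	A/A	A/-	A/A	A/A	A/A	A/A	A/A	G/G	A/A	G/G	R/R	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	A/A	1
WMHL4	Chr2	24830110	T	T/T	T/T	T/T	T/-	T/T	T/T	T/T	T/T	T/T	T/T	T/T	C/C	Y/Y	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	T/T	1
WMHL5	Chr2	24843410	A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	G/G	R/R	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	A/A	1
WMHL6	Chr2	24877311	T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	C/C	Y/Y	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	T/T	1
WMHL7	Chr2	24886838	C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	T/T	Y/Y	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	C/C	1
WMHL8	Chr4	8923655	A	A/A	A/A	A/A	A/-	A/A	A/A	A/A	A/A	A/A	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	1
WMHL9	Chr4	9807020	C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	1
WMHL10	Chr4	9807385	A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	1
WMHL11	Chr4	10209760	T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	C/C	C/C	C/C	Y/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	0.96
WMHL12	Chr4	10826029	G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	1
WMHL13	Chr4	10838374	A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	1
WMHL14	Chr5	20321987	A	A/A	A/A	A/A	G/G	A/A	A/A	A/A	A/A	A/A	G/G	G/G	G/G	A/A	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	1
WMHL15	Chr5	21363473	A	A/A	A/A	A/A	G/-	A/A	A/A	A/A	A/A	A/A	G/G	G/G	G/G	A/A	G/G	G/G	G/G	G/G	G/G	G/-	G/G	G/G	G/G	G/G	G/G	1
WMHL16	Chr9	22158134	G	G/G	G/G	G/G	A/-	G/G	G/G	A/A	G/G	G/G	G/G	G/G	A/A	G/G	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	G/G	G/G	1
WMHL17	Chr9	22239355	C	C/C	C/C	C/C	A/-	C/C	C/C	C/C	C/C	C/C	C/C	C/C	A/A	C/C	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	C/A	C/C	0.96
WMHL18	Chr10	26477503	T	C/C	C/C	C/C	C/C	C/C	C/C	T/T	C/C	C/C	T/T	T/T	T/T	C/C	T/T	T/T	C/C	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	1
WMHL19	Chr10	26681481	C	T/T	T/T	T/T	T/T	T/T	T/T	C/C	T/T	T/T	C/C	C/C	C/C	T/T	C/C	C/C	T/T	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	1
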