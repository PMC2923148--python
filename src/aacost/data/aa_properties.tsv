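# Physico-chemical properties of the 20 standard amino acids.
# carbon/nitrogen/sulphur: atom counts of the free amino acid.
# mol_weight: molecular weight of the free amino acid in Daltons.
# trna_genes: genomic tRNA gene copy number decoding the residue's codons
#   in S. cerevisiae (nuclear tRNA gene complement).
one	three	carbon	nitrogen	sulphur	mol_weight	trna_genes
A	ala	3	1	0	89.1	16
R	arg	6	4	0	174.2	19
N	asn	4	2	0	132.1	10
D	asp	4	1	0	133.1	16
C	cys	3	1	1	121.2	4
Q	gln	5	2	0	146.2	9
E	glu	5	1	0	147.1	16
G	gly	2	1	0	75.1	21
H	his	6	3	0	155.2	7
I	ile	6	1	0	131.2	15
L	leu	6	1	0	131.2	17
K	lys	6	2	0	146.2	21
M	met	5	1	1	149.2	10
F	phe	9	1	0	165.2	10
P	pro	5	1	0	115.1	10
S	ser	3	1	0	105.1	16
T	thr	4	1	0	119.1	15
W	trp	11	2	0	204.2	6
Y	tyr	9	1	0	181.2	8
V	val	5	1	0	117.2	14
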