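# Eight measures of amino acid biosynthetic cost for the 20 standard residues.
# abs_glc / rel_glc: FBA-derived absolute and relative cost under simulated
#   glucose limitation for S. cerevisiae (iND750), rescaled by growth rate
#   (abs_glc unitless, rel_glc in mmol per gram dry weight).
# ag_energy: Akashi & Gojobori (2002) energetic cost (~P high-energy bonds).
# cw_energy / cw_steps: Craig & Weber (1998) energetic cost and number of
#   biosynthetic steps from central metabolism.
# wagner_ferm / wagner_resp: Wagner (2005) fermentative and respiratory
#   energetic costs (~P).
# mol_weight: molecular weight in Daltons, used as a cost proxy by
#   Seligmann (2003).
# Values are printed 3-significant-figure table entries.
residue	abs_glc	rel_glc	ag_energy	cw_energy	cw_steps	wagner_ferm	wagner_resp	mol_weight
ala	0.50	0.223	11.7	12.5	1	2	14.5	89.1
arg	1.39	0.218	27.3	18.5	10	13	20.5	174.2
asn	0.79	0.078	14.7	4	1	6	18.5	132.1
asp	0.61	0.178	12.7	1	1	3	15.5	133.1
cys	0.75	0.005	24.7	24.5	9	13	26.5	121.2
gln	0.92	0.095	16.3	9.5	2	3	10.5	146.2
glu	0.86	0.254	15.3	8.5	1	2	9.5	147.1
gly	0.31	0.087	11.7	14.5	4	1	14.5	75.1
his	1.46	0.094	38.3	33	1	5	29	155.2
ile	1.21	0.226	32.3	20	11	14	38	131.2
leu	1.21	0.348	27.3	33	7	4	37	131.2
lys	1.31	0.366	30.3	18.5	10	12	36	146.2
met	1.25	0.062	34.3	18.5	9	24	36.5	149.2
phe	1.84	0.240	52.0	63	9	10	61	165.2
pro	0.99	0.159	20.3	12.5	4	7	14.5	115.1
ser	0.49	0.089	11.7	15	3	1	14.5	105.1
thr	0.69	0.128	18.7	6	6	9	21.5	119.1
trp	2.39	0.066	74.3	78.5	12	14	75.5	204.2
tyr	1.77	0.176	50.0	56.5	9	8	59	181.2
val	0.96	0.246	23.3	25	4	4	29	117.2
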