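gene_symbol	gene_name	chrom	start_mb	end_mb	strand	traits
ARSJ	Arylsulfatase Family, Member J	6	12.720022	12.803721	.	CS,CSm
LAP3	Leucine Aminopeptidase 3	6	38.574590	38.600027	.	PO
NCAPG	Non-SMC Condensin I Complex, Subunit G	6	38.765969	38.812051	.	PO
LCORL	Ligand Dependent Nuclear Receptor Corepressor-Like	6	38.840894	38.992112	.	PO
FOXG1	Forkhead Box G1	21	39.655563	39.657038	.	CS
NDE1	nudE Neurodevelopment Protein 1	25	14.189695	14.237237	+	CS,CSm
MYH11	Myosin 11	25	14.218281	14.343745	-	CS,CSm
NRG1	Neuroregulin 1	27	27.624065	27.702831	.	CS,CSm
SLC16A9	Solute carrier family 16, member 9	28	15.428478	15.474740	.	CSm
GC	Group-Specific Component	6	88.695940	88.739180	-	WWm,MY,US
SLC11A2	Solute carrier family 11, member 2	5	29.012107	29.034478	.	MY
RGP1	Retrograde Golgi Transport Homolog	8	60.328033	60.333812	.	WWm,US,MY
KCNJ2	Potassium channel, inwardly rectifying subfamily J, member 2	19	61.185603	61.195897	.	WWm,US
KCNJ16	Potassium channel, inwardly rectifying subfamily J, member 16	19	61.226690	61.229571	.	WWm,US
TRIO	Trio Rho Guanine Nucleotide Exchange Factor	20	58.714145	58.945942	.	WWm,MY
ANXA7	Annexin A7	28	29.552050	29.573976	.	WWm
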