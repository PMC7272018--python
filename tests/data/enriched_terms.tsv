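term	count	p_value	collection	direction
GO:0044267~cellular protein metabolic process	250	9.04E-16	GO	up
GO:0015031~protein transport	100	5.37E-11	GO	up
GO:0006886~intracellular protein transport	60	4.02E-10	GO	up
GO:0016070~RNA metabolic process	104	2.08E-07	GO	up
GO:0043632~modification-dependent macromolecule catabolic process	70	1.09E-06	GO	up
GO:0030163~protein catabolic process	73	2.57E-06	GO	up
GO:0051246~regulation of protein metabolic process	66	3.14E-06	GO	up
GO:0006396~RNA processing	66	3.47E-06	GO	up
GO:0044257~cellular protein catabolic process	70	6.25E-06	GO	up
GO:0016071~mRNA metabolic process	48	1.43E-05	GO	up
GO:0006397~mRNA processing	41	9.44E-05	GO	up
GO:0006412~translation	41	1.83E-04	GO	up
GO:0006464~protein modification process	131	2.20E-04	GO	up
GO:0006259~DNA metabolic process	54	6.85E-04	GO	up
GO:0032268~regulation of cellular protein metabolic process	50	0.001416	GO	up
GO:0042981~regulation of apoptosis	75	0.002679	GO	up
GO:0043067~regulation of programmed cell death	75	0.003472	GO	up
GO:0010605~negative regulation of macromolecule metabolic process	68	0.005107	GO	up
GO:0031325~positive regulation of cellular metabolic process	79	0.00553	GO	up
hsa00020: Citrate cycle (TCA cycle)	10	2.33E-04	KEGG	up
hsa04120: Ubiquitin mediated proteolysis	23	2.74E-04	KEGG	up
hsa04142: Lysosome	19	0.001623	KEGG	up
hsa03040: Spliceosome	19	0.003749	KEGG	up
hsa00510: N-Glycan biosynthesis	10	0.004849	KEGG	up
hsa03018: RNA degradation	11	0.006855	KEGG	up
hsa00190: Oxidative phosphorylation	18	0.011546	KEGG	up
hsa05210: Colorectal cancer	13	0.016526	KEGG	up
hsa05016: Huntington's disease	22	0.018547	KEGG	up
hsa05012: Parkinson's disease	16	0.041203	KEGG	up
hsa00230: Purine metabolism	18	0.048018	KEGG	up
GO:0009887~organ morphogenesis	44	6.00E-04	GO	down
GO:0019932~second-messenger-mediated signaling	23	0.001072	GO	down
GO:0030808~regulation of nucleotide biosynthetic process	14	0.001434	GO	down
GO:0007242~intracellular signaling cascade	80	0.001696	GO	down
GO:0006140~regulation of nucleotide metabolic process	14	0.002324	GO	down
GO:0045761~regulation of adenylate cyclase activity	12	0.004139	GO	down
GO:0048705~skeletal system morphogenesis	13	0.00487	GO	down
GO:0042391~regulation of membrane potential	14	0.007974	GO	down
hsa04080: Neuroactive ligand-receptor interaction	26	5.02E-04	KEGG	down
hsa04650: Natural killer cell mediated cytotoxicity	16	0.001677	KEGG	down
hsa04512: ECM-receptor interaction	11	0.006667	KEGG	down
hsa04660: T cell receptor signaling pathway	12	0.014253	KEGG	down
hsa04912: GnRH signaling pathway	11	0.018809	KEGG	down
hsa04020: Calcium signaling pathway	16	0.021719	KEGG	down
hsa05340: Primary immunodeficiency	6	0.024776	KEGG	down
hsa04210: Apoptosis	9	0.047056	KEGG	down
hsa04510: Focal adhesion	16	0.049391	KEGG	down
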