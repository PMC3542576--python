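# Enzymatic activities required for the degradation of soluble galactoglucomannan
# by Aspergillus niger: fifteen gene records spanning six activities, with
# published Uniprot / CBS 513.88 / ATCC 1015 identifiers.
ec	name	cazy	mode	gene_name	uniprot	cbs_id	atcc_id	characterized	refs	ambiguous_probe_group
3.2.1.78	Endo-1,4-β-D-mannanase	GH5	endo			An05g01320	50378	yes	B22
3.2.1.78	Endo-1,4-β-D-mannanase	GH26	endo			An15g07760	40875	no
3.2.1.25	β-mannosidase	GH2	exo_nonreducing			An01g06630	172587	no
3.2.1.25	β-mannosidase	GH2	exo_nonreducing	mndA	Q9UUZ3	An11g06540	138876	yes	B23;B24;B25
3.2.1.22	α-galactosidase	GH36	debranching	aglC	Q9UUZ4	An09g00260	212736	yes	B24;B26
3.2.1.22	α-galactosidase	GH27	debranching			An01g01320	172232	no
3.2.1.22	α-galactosidase	GH27	debranching	aglB	Q9Y865	An02g11150	207264	yes	B26;B27
3.2.1.22	α-galactosidase	GH27	debranching	aglA	A2QL72	An06g00170	37736	yes	B26;B28;B29
3.2.1.21	β-glucosidase	GH3	exo_nonreducing			An15g04800	181816	no
3.2.1.21	β-glucosidase	GH3	exo_nonreducing			An17g00520	129891	no
3.2.1.21	β-glucosidase	GH3	exo_nonreducing	bgl1	A2RAL4	An18g03570	56782	yes	B30;B31;B32;B33;B34;B35;B36
3.2.1.23	β-galactosidase	GH35	exo_nonreducing			An01g10350	46429	no
3.2.1.23	β-galactosidase	GH35	exo_nonreducing			An14g05820	41910	no
3.2.1.23	β-galactosidase	GH35	exo_nonreducing	lacA	P29853	An01g12150	51764	yes	B26
3.1.1.6	Acetyl esterase	CE16	esterase			An02g02540	N/A	no
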