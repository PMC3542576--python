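# Framework-wide gene catalog: at least one A. niger gene per registry activity,
# so that every packaged polysaccharide structure can be overlaid with expression
# statuses.  Gene names are the published ones where the literature names them.
# SYNTHETIC: sequence identifiers other than the fifteen soluble-galactoglucomannan
# records (and An02g02540) are placeholders of the form An95gNNNNN / 9NNNNN and do
# not correspond to real genome coordinates.
ec	name	cazy	mode	gene_name	uniprot	cbs_id	atcc_id	characterized	refs	ambiguous_probe_group
3.2.1.1	α-amylase	GH13	endo	amyA		An95g00010	900010	yes	B9	amy
3.2.1.1	α-amylase	GH13	endo	amyB		An95g00020	900020	yes	B9	amy
3.2.1.41	pullulanase	GH13	endo			An95g00030	900030	no
3.2.1.3	glucoamylase	GH15	exo_nonreducing	glaA		An95g00040	900040	yes	B9
3.2.1.20	α-glucosidase	GH31	exo_nonreducing	agdA		An95g00050	900050	yes	B9
3.2.1.20	α-glucosidase	GH31	exo_nonreducing	aglU		An95g00055	900055	no
3.2.1.7	endo-inulinase	GH32	endo	inuA		An95g00060	900060	yes	B7
3.2.1.80	exo-inulinase	GH32	exo_nonreducing	inuE		An95g00070	900070	yes	B8
3.2.1.4	endo-1,4-β-glucanase	GH12	endo	eglA		An95g00080	900080	yes	B51
3.2.1.4	endo-1,4-β-glucanase	GH5	endo	eglB		An95g00090	900090	no
3.2.1.21	β-glucosidase	GH3	exo_nonreducing	bgl1	A2RAL4	An18g03570	56782	yes	B30;B31;B32
3.2.1.78	Endo-1,4-β-D-mannanase	GH5	endo			An05g01320	50378	yes	B22
3.2.1.78	Endo-1,4-β-D-mannanase	GH26	endo			An15g07760	40875	no
3.2.1.25	β-mannosidase	GH2	exo_nonreducing	mndA	Q9UUZ3	An11g06540	138876	yes	B23;B24;B25
3.2.1.22	α-galactosidase	GH27	debranching	aglA	A2QL72	An06g00170	37736	yes	B26;B28;B29
3.2.1.23	β-galactosidase	GH35	exo_nonreducing	lacA	P29853	An01g12150	51764	yes	B26
3.1.1.6	Acetyl esterase	CE16	esterase			An02g02540	N/A	no
3.2.1.8	endo-1,4-β-xylanase	GH11	endo	xlnB		An95g00100	900100	yes	B41
3.2.1.8	endo-1,4-β-xylanase	GH10	endo	xynA		An95g00110	900110	yes	B41
3.2.1.37	β-xylosidase	GH3	exo_nonreducing	xlnD		An95g00120	900120	yes	B41
3.2.1.55	α-arabinofuranosidase	GH51	exo_nonreducing	abfA		An95g00130	900130	yes	B5;B10
3.2.1.55	α-arabinofuranosidase	GH54	exo_nonreducing	abfB		An95g00140	900140	yes	B5;B11
3.2.1.55	arabinoxylan arabinofuranohydrolase	GH62	debranching	axhA		An95g00150	900150	yes	B41
3.2.1.139	α-glucuronidase	GH67	debranching	aguA		An95g00160	900160	yes	B13
3.1.1.72	acetyl xylan esterase	CE1	esterase	axeA		An95g00170	900170	no
3.2.1.99	endo-1,5-α-arabinanase	GH43	endo	abnA		An95g00180	900180	yes	B5
3.2.1.89	endo-1,4-β-galactanase	GH53	endo			An95g00190	900190	no
	endo-1,3-β-galactanase	GH43	endo			An95g00200	900200	no
3.2.1.31	β-glucuronidase	GH79	debranching			An95g00210	900210	no
3.1.1.73	feruloyl esterase	CE1	esterase	faeB		An95g00220	900220	yes	B5
3.2.1.15	endo-polygalacturonase	GH28	endo	pgaI		An95g00230	900230	yes	B5
3.2.1.67	exo-polygalacturonase	GH28	exo_nonreducing	pgaX		An95g00240	900240	yes	B5
3.1.1.11	pectin methyl esterase	CE8	esterase	pmeA		An95g00250	900250	yes	B5
3.2.1.171	endo-rhamnogalacturonase	GH28	endo	rhgA		An95g00260	900260	no
3.2.1.40	α-rhamnosidase	GH78	exo_nonreducing			An95g00270	900270	no
3.1.1.86	rhamnogalacturonan acetyl esterase	CE12	esterase	rgaeA		An95g00280	900280	yes	B12
3.2.1.177	α-xylosidase	GH31	debranching			An95g00290	900290	no
3.2.1.51	α-fucosidase	GH95	debranching			An95g00300	900300	no
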