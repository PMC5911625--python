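accession	year	area	platform	set	total	tumor	nontumor
GSE27155	2011	USA	GPL96	training	99	78	21
GSE33630	2012	Belgium	GPL570	training	105	60	45
GSE35570	2015	Poland	GPL570	training	116	65	51
GSE60542	2015	Belgium	GPL570	training	63	33	30
GSE82208	2017	Poland	GPL570	training	52	27	25
GSE29265	2012	Belgium	GPL570	test	49	29	20
GSE3467	2005	USA	GPL570	test	18	9	9
GSE3678	2006	USA	GPL570	test	14	7	7
GSE53157	2013	Portugal	GPL570	test	27	24	3
GSE5364	2008	Singapore	GPL96	test	51	35	16
GSE58545	2015	Poland	GPL96	test	45	27	18
GSE6004	2006	USA	GPL570	test	18	14	4
GSE65144	2015	USA	GPL570	test	25	12	13
TCGA	2015	USA	IlluminaHiSeq	validation	564	505	59
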