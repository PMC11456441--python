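ensembl_id	symbol	category	localization
ENSG00000017427	IGF1	IGFs	Extracellular matrix
ENSG00000167244	IGF2	IGFs	Extracellular matrix
ENSG00000140443	IGF1R	IGF-Rs	Cytomembrane
ENSG00000197081	IGF2R	IGF-Rs	Cytomembrane
ENSG00000146678	IGFBP1	IGFBPs	Extracellular matrix
ENSG00000115457	IGFBP2	IGFBPs	Extracellular matrix
ENSG00000146674	IGFBP3	IGFBPs	Extracellular matrix
ENSG00000141753	IGFBP4	IGFBPs	Extracellular matrix
ENSG00000115461	IGFBP5	IGFBPs	Extracellular matrix
ENSG00000167779	IGFBP6	IGFBPs	Extracellular matrix
ENSG00000142208	AKT1	PI3K/AKT	Cytosol
ENSG00000145675	PIK3R1	PI3K/AKT	Cytosol
ENSG00000108443	RPS6KB1	PI3K/AKT	Cytosol
ENSG00000102882	MAPK3	MAPK	Cytosol
ENSG00000100030	MAPK1	MAPK	Cytosol
ENSG00000169032	MAP2K1	MAPK	Cytosol
ENSG00000126934	MAP2K2	MAPK	Cytosol
ENSG00000187840	EIF4EBP1	MAPK	Cytosol
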