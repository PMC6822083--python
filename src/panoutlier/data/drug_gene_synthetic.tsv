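symbol	drug	source
FLT3	midostaurin	CIViC
FLT3	sorafenib	My Cancer Genome
KIT	imatinib	CIViC
PDGFRA	imatinib	CIViC
PDGFRB	sunitinib	Cancer Commons
KDR	pazopanib	Cancer Commons
ALK	crizotinib	CIViC
ALK	ceritinib	My Cancer Genome
EGFR	erlotinib	Cancer Commons
ERBB2	trastuzumab	CIViC
FGFR1	ponatinib	Cancer Commons
FGFR2	erdafitinib	My Cancer Genome Clinical Trial
MET	crizotinib	CIViC
RET	cabozantinib	My Cancer Genome
ROS1	crizotinib	CIViC
NTRK1	larotrectinib	My Cancer Genome Clinical Trial
IGF1R	linsitinib	My Cancer Genome Clinical Trial
CSF1R	pexidartinib	My Cancer Genome Clinical Trial
JAK1	ruxolitinib	My Cancer Genome
JAK2	ruxolitinib	My Cancer Genome
CDK4	palbociclib	CIViC
CDK6	palbociclib	CIViC
AURKA	alisertib	My Cancer Genome Clinical Trial
BTK	ibrutinib	My Cancer Genome
SYK	fostamatinib	Cancer Commons
PIK3CA	alpelisib	CIViC
MTOR	everolimus	My Cancer Genome
BRAF	vemurafenib	CIViC
BRAF	dabrafenib	My Cancer Genome
MAP2K1	trametinib	CIViC
SMO	vismodegib	CIViC
BCL2	venetoclax	My Cancer Genome
MDM2	idasanutlin	My Cancer Genome Clinical Trial
HSP90AA1	ganetespib	My Cancer Genome Clinical Trial
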