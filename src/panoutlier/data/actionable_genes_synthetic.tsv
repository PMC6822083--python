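symbol	class	pathway_group
FLT3	direct	RTK
KIT	direct	RTK
PDGFRA	direct	RTK
PDGFRB	direct	RTK
KDR	direct	RTK
ALK	direct	RTK
EGFR	direct	RTK
ERBB2	direct	RTK
ERBB3	direct	RTK
ERBB4	direct	RTK
FGFR1	direct	RTK
FGFR2	direct	RTK
FGFR3	direct	RTK
FGFR4	direct	RTK
MET	direct	RTK
RET	direct	RTK
ROS1	direct	RTK
NTRK1	direct	RTK
NTRK2	direct	RTK
NTRK3	direct	RTK
IGF1R	direct	RTK
AXL	direct	RTK
CSF1R	direct	RTK
JAK1	direct	JAK-STAT
JAK2	direct	JAK-STAT
JAK3	direct	JAK-STAT
CDK4	direct	cell-cycle
CDK6	direct	cell-cycle
AURKA	direct	cell-cycle
AURKB	direct	cell-cycle
PLK1	direct	cell-cycle
BTK	direct	BCR
SYK	direct	BCR
PIK3CA	direct	PI3K-AKT-mTOR
MTOR	direct	PI3K-AKT-mTOR
BRAF	direct	RAS-RAF-MEK
MAP2K1	direct	RAS-RAF-MEK
PTCH1	indirect	SHH
SHH	indirect	SHH
GLI1	indirect	SHH
GLI2	indirect	SHH
SMO	indirect	SHH
KRAS	indirect	RAS-RAF-MEK
NRAS	indirect	RAS-RAF-MEK
HRAS	indirect	RAS-RAF-MEK
RAF1	indirect	RAS-RAF-MEK
ARAF	indirect	RAS-RAF-MEK
MAP2K2	indirect	RAS-RAF-MEK
MAPK1	indirect	RAS-RAF-MEK
MAPK3	indirect	RAS-RAF-MEK
NF1	indirect	RAS-RAF-MEK
PIK3CB	indirect	PI3K-AKT-mTOR
PIK3CD	indirect	PI3K-AKT-mTOR
PIK3R1	indirect	PI3K-AKT-mTOR
AKT1	indirect	PI3K-AKT-mTOR
AKT2	indirect	PI3K-AKT-mTOR
AKT3	indirect	PI3K-AKT-mTOR
PTEN	indirect	PI3K-AKT-mTOR
RICTOR	indirect	PI3K-AKT-mTOR
RPTOR	indirect	PI3K-AKT-mTOR
TSC1	indirect	PI3K-AKT-mTOR
TSC2	indirect	PI3K-AKT-mTOR
RHEB	indirect	PI3K-AKT-mTOR
STAT1	indirect	JAK-STAT
STAT3	indirect	JAK-STAT
STAT5A	indirect	JAK-STAT
STAT5B	indirect	JAK-STAT
IL6	indirect	JAK-STAT
IL7R	indirect	JAK-STAT
CRLF2	indirect	JAK-STAT
CD79A	indirect	BCR
CD79B	indirect	BCR
BLNK	indirect	BCR
LYN	indirect	BCR
PAX5	indirect	BCR
CCND1	indirect	cell-cycle
CCND2	indirect	cell-cycle
CCND3	indirect	cell-cycle
CCNE1	indirect	cell-cycle
CDK2	indirect	cell-cycle
E2F1	indirect	cell-cycle
RB1	indirect	cell-cycle
HSP90AA1	indirect	HSP
HSP90AB1	indirect	HSP
HSP90B1	indirect	HSP
HSPA5	indirect	HSP
BCL2	indirect	BCL2-MDM2
BCL2L1	indirect	BCL2-MDM2
MCL1	indirect	BCL2-MDM2
MDM2	indirect	BCL2-MDM2
MDM4	indirect	BCL2-MDM2
TP53	indirect	BCL2-MDM2
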