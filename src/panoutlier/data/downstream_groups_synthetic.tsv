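gene	downstream_groups
NRAS	RAS-RAF-MEK;cell-cycle;BCL2-MDM2
KRAS	RAS-RAF-MEK;cell-cycle;BCL2-MDM2
HRAS	RAS-RAF-MEK;cell-cycle;BCL2-MDM2
BCR-ABL1	PI3K-AKT-mTOR;BCR
PAX5-JAK2	JAK-STAT
NF1	SHH;RTK
SMARCB1	RTK
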