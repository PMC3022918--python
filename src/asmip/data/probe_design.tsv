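gene	specificity	n_constitutive	n_alternative
CAMK2D	neural	8	5
CLTB	neural	3	3
EHBP1	neural	8	4
ERC1	neural	8	10
FEZ2	neural	2	9
MARK4	neural	8	3
MINK1	neural	11	10
MLLT4	neural	9	10
MYH10	neural	15	8
MYO6	neural	10	6
TPD52	neural	3	6
TPM1	muscle	5	7
TPM2	muscle	5	6
TPM3	muscle	4	6
ACTB	control	5	0
GAPDH	control	8	0
TUBA1B	control	3	0
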