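# Eight-gene CCF recurrence risk model (ESCC, disease-free survival)
# risk score = sum(coefficient * gene CCF); groups: low <= cutoff1 < intermediate <= cutoff2 < high
# cutoffs	-0.0565	0.168
gene	coefficient
GPR98	1.18
LAMA1	1.31
IFT140	1.42
MUC17	1.18
PTPRB	1.78
AHNAK2	-1.37
PREX2	-2.78
SPATA31D1	-3.02
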