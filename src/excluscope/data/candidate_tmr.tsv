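gene	cohort	or	pval	pleiotropy_pval	heterogeneity_pval
PGAP3	discovery	1.048	0.009	0.192	0.463
VAMP3	discovery	1.037	0.009	0.525	0.366
DRAM2	discovery	0.966	0.001	0.353	0.448
RNASEH2C	discovery	0.964	0.047	0.686	0.119
PYROXD2	discovery	0.944	0.046	0.596	0.237
PGAP3	replication	1.112	0.018	0.194	0.392
VAMP3	replication	1.126	0.005	0.341	0.374
DRAM2	replication	0.951	0.043	0.434	0.633
RNASEH2C	replication	0.884	0.004	0.463	0.266
PYROXD2	replication	0.841	0.016	0.436	0.383
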