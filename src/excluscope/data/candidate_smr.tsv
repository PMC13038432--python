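gene	cohort	top_snp	b_smr	p_smr	p_heidi
PGAP3	discovery	rs2952152	0.072	0.005	0.678
VAMP3	discovery	rs1048785	0.054	0.038	0.258
DRAM2	discovery	rs3762374	-0.028	0.004	0.454
RNASEH2C	discovery	rs11227248	-0.066	0.012	0.856
PYROXD2	discovery	rs7913541	0.041	0.044	0.898
PGAP3	replication	rs2952152	0.157	0.011	0.173
VAMP3	replication	rs1048785	0.160	0.005	0.582
DRAM2	replication	rs3762374	-0.070	0.003	0.456
RNASEH2C	replication	rs11227248	-0.241	0.001	0.075
PYROXD2	replication	rs7913541	0.189	0.001	0.339
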