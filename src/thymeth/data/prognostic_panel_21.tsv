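probe_id	gene	promoter_region	delta_pdtc_atc_vs_nt	delta_pp_vs_gp	dlda_score
cg00119186	OR6K2	1stExon	-0.411	-0.105	-16.72
cg08905487	LAIR2	TSS200	-0.406	-0.134	-12.14
cg02710090	PFKFB2	TSS1500	-0.253	-0.109	-11.41
cg07531287	OR4K15	1stExon	-0.280	-0.112	-10.68
cg25730098	NLRP11	5UTR	-0.321	-0.118	-10.65
cg03178489	OR9G4	1stExon	-0.307	-0.104	-9.33
cg08231096	THSD7B	TSS200	-0.352	-0.101	-9.23
cg07598464	OR2M3	1stExon	-0.388	-0.131	-8.41
cg21966764	OR52B2	TSS1500	-0.263	-0.110	-7.31
cg06846214	OR2T6	TSS1500	-0.337	-0.109	-6.38
cg20199836	FFAR2	TSS200	-0.369	-0.102	-6.06
cg17372806	RTN3	TSS1500	-0.330	-0.103	-5.81
cg03316101	OR52M1	1stExon	-0.309	-0.123	-5.03
cg01687040	DCD	TSS1500	-0.355	-0.103	-4.75
cg04103514	ADGRE2	TSS200	-0.379	-0.122	-4.70
cg06457736	HRH1	TSS200	-0.460	-0.120	-3.48
cg19628988	CXXC5	5UTR	-0.362	-0.104	-3.28
cg14115756	GPR21	TSS1500	0.457	0.117	4.07
cg03560685	MBP	TSS1500	0.513	0.109	4.98
cg22705929	YPEL4	TSS1500	0.324	0.122	5.66
cg05884711	ATP6V0C	TSS1500	0.341	0.191	9.60
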