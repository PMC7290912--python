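locus	tnpa_type	tnpb_type	le	re	tnpa_locus_id	tnpb_locus_id	strand_class
1	Type 2	1B	consensus	type 2	HALSA_RS01255	HALSA_RS01260	Lead
2	Type 5	2C	consensus	type 1	N/A	HALSA_RS01330	Lead
3	Type 5	2C	consensus	type 1	N/A	HALSA_RS01515	Lag
4	Type 5	2A	consensus	type 2	N/A	HALSA_RS01645	Lead
5	Type 5	1A	consensus	type 1	HALSA_RS02280	HALSA_RS02275	Lead
6	Type 5	2A	consensus	type 2	HALSA_RS02590	HALSA_RS02585	Lag
7	IS200	N/A	unknown	unknown	HALSA_RS03110	N/A	Lag
8	Type 5	1A	consensus	type 1	N/A	HALSA_RS03165	Lag
9	Type 1	2A	consensus	type 1	HALSA_RS03745	HALSA_RS03750	Lag
10	Type 5	1A	consensus	type 1	N/A	HALSA_RS04080	Lag
11	Type 5	3	consensus	type 1	N/A	HALSA_RS12615	Lag
12	Type 5	3	consensus	type 1	N/A	HALSA_RS12630	Lag
13	Type 3	2A'	consensus	type 1	HALSA_RS12635	HALSA_RS05500	Lag
14	Type 5	MISC	consensus	type 2	N/A	N/A	Lead
15	Type 4	3'	consensus	MISC	HALSA_RS12645	HALSA_RS12715	Lead
16	Type 5	1A	consensus	type 1	N/A	HALSA_RS06215	Lag
17	Type 5	2B	consensus	type 1	N/A	HALSA_RS07530	Lag
18	Type 5	2B'	consensus	type 1	N/A	HALSA_RS08275	Lead
19	Type 5	2B	consensus	type 1	N/A	HALSA_RS08865	Lag
20	Type 2	2B	consensus	type 1	HALSA_RS11165	HALSA_RS11170	Lead
21	Type 5	3	consensus	type 2	N/A	HALSA_RS12685	Lead
22	Type 5	3	consensus	type 1	N/A	HALSA_RS12690	Lead
23	Type 5	3	consensus	type 1	N/A	HALSA_RS12700	Lag
PATE	NA	NA	Hairpin	type 2	N/A	N/A	Lag
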