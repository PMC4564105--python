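sample_id	individual_id	family_id	cohort	disease	component	passage	replicate	total_reads	alt_reads	af_pct
1_p0	1	1	WM_FAMILY	MGUS	IgM	0	1	18037	138	0.77
1_p4	1	1	WM_FAMILY	MGUS	IgM	4	1	22478	422	1.88
1_p9	1	1	WM_FAMILY	MGUS	IgM	9	1	11923	216	1.81
3_p0	3	2	WM_FAMILY	WM	NONE	0	1	23027	76	0.33
3_p4	3	2	WM_FAMILY	WM	NONE	4	1	18091	685	3.79
3_p9	3	2	WM_FAMILY	WM	NONE	9	1	25153	1814	7.21
4_p0	4	2	WM_FAMILY	WM	NONE	0	1	22352	161	0.72
4_p4	4	2	WM_FAMILY	WM	NONE	4	1	13306	479	3.60
4_p9	4	2	WM_FAMILY	WM	NONE	9	1	13195	308	2.33
6_p0	6	3	WM_FAMILY	MGUS	IgG	0	1	19943	258	1.29
6_p4	6	3	WM_FAMILY	MGUS	IgG	4	1	20819	3544	17.02
6_p9	6	3	WM_FAMILY	MGUS	IgG	9	1	11066	1933	17.47
12_p0	12	18	WM_FAMILY	MGUS	IgG	0	1	13014	64	0.49
12_p4	12	18	WM_FAMILY	MGUS	IgG	4	1	15566	135	0.87
12_p9	12	18	WM_FAMILY	MGUS	IgG	9	1	18559	115	0.62
14_p0	14	11	WM_FAMILY	WM	NONE	0	1	18473	56	0.30
14_p4	14	11	WM_FAMILY	WM	NONE	4	1	16634	73	0.44
14_p9	14	11	WM_FAMILY	WM	NONE	9	1	11912	52	0.44
16_p0	16	13	WM_FAMILY	WM	NONE	0	1	18797	89	0.47
16_p4	16	13	WM_FAMILY	WM	NONE	4	1	13533	304	2.25
16_p9	16	13	WM_FAMILY	WM	NONE	9	1	19223	503	2.62
19_p0	19	14	WM_FAMILY	MGUS	IgM	0	1	17704	1116	6.30
19_p4	19	14	WM_FAMILY	MGUS	IgM	4	1	17832	1097	6.15
19_p9	19	14	WM_FAMILY	MGUS	IgM	9	1	15712	511	3.25
20_p0	20	14	WM_FAMILY	WM	NONE	0	1	20620	71	0.34
20_p4	20	14	WM_FAMILY	WM	NONE	4	1	14142	158	1.12
20_p9	20	14	WM_FAMILY	WM	NONE	9	1	6563	49	0.75
21_p0	21	15	WM_FAMILY	WM	NONE	0	1	14622	66	0.45
21_p4	21	15	WM_FAMILY	WM	NONE	4	1	26112	1848	7.08
21_p9	21	15	WM_FAMILY	WM	NONE	9	1	16425	1328	8.09
34_p0	34	11	WM_FAMILY	WM	NONE	0	1	18208	67	0.37
34_p4	34	11	WM_FAMILY	WM	NONE	4	1	11832	612	5.17
34_p9	34	11	WM_FAMILY	WM	NONE	9	1	17552	5961	33.96
35_p0	35	16	WM_FAMILY	WM	NONE	0	1	26473	57	0.22
35_p4	35	16	WM_FAMILY	WM	NONE	4	1	16841	130	0.77
35_p9	35	16	WM_FAMILY	WM	NONE	9	1	29768	334	1.12
37_p0	37	5	WM_FAMILY	WM	NONE	0	1	28694	87	0.30
37_p4	37	5	WM_FAMILY	WM	NONE	4	1	13437	459	3.42
37_p9	37	5	WM_FAMILY	WM	NONE	9	1	23214	131	0.56
45_p0	45	5	WM_FAMILY	MGUS	IgM	0	1	16449	1400	8.51
45_p4	45	5	WM_FAMILY	MGUS	IgM	4	1	22636	7335	32.40
45_p9	45	5	WM_FAMILY	MGUS	IgM	9	1	20127	7531	37.42
46_p0	46	9	WM_FAMILY	MGUS	IgM	0	1	16520	49	0.30
46_p4	46	9	WM_FAMILY	MGUS	IgM	4	1	32414	252	0.78
46_p9	46	9	WM_FAMILY	MGUS	IgM	9	1	29725	271	0.91
A_p0	A		MM_FAMILY	MGUS	IgM	0	1	34466	104	0.30
A_p4	A		MM_FAMILY	MGUS	IgM	4	1	17563	758	4.32
A_p9	A		MM_FAMILY	MGUS	IgM	9	1	24381	483	1.98
B_p0	B		MM_FAMILY	MGUS	IgM	0	1	22647	123	0.54
B_p4	B		MM_FAMILY	MGUS	IgM	4	1	19072	609	3.19
B_p9	B		MM_FAMILY	MGUS	IgM	9	1	48700	528	1.08
C_p0	C		MM_FAMILY	MGUS	IgG	0	1	12142	36	0.30
C_p4	C		MM_FAMILY	MGUS	IgG	4	1	9677	1274	13.17
C_p9	C		MM_FAMILY	MGUS	IgG	9	1	9449	1020	10.79
D_p0	D		MM_FAMILY	MGUS	IgA	0	1	15617	37	0.24
D_p4	D		MM_FAMILY	MGUS	IgA	4	1	16424	208	1.27
D_p9	D		MM_FAMILY	MGUS	IgA	9	1	9656	67	0.69
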