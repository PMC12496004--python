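sample_id	gene	timepoint	mmr_status	loh	second_hit	tmb	hypermutated	ref_normal
LEC1_EEC	MLH1	0	dMMR	No	MLH1:nonsense:7	6.1	0	1
LEC1_CAH	MLH1	0	pMMR	No	[MLH1:nonsense:2]	0.3	0	1
LEC2_EEC	MSH2	0	dMMR	No	MSH2:splice:24	16.6	1	0
LEC3_EEC	MLH1	0	dMMR	No	MLH1:splice:17	11.6	1	0
LEC4_EEC	MLH1	0	dMMR	No	MLH1:frameshift:27	17.0	1	0
LEC5_EEC	MLH1	0	dMMR	No	MLH1:in_frame_deletion:28	13.6	1	0
LEC6_CCEC1	MLH1	-1	dMMR	No	MLH1:missense:16	12.5	1	0
LEC6_CCEC2	MLH1	0	dMMR	No	MLH1:missense:20	14.7	1	0
LEC8_CAH1	MLH1	-1	dMMR	LOH	None	31.1	1	0
LEC8_CAH2	MLH1	0	dMMR	pLOH	None	18.4	1	0
LEC8_CAH3	MLH1	0	dMMR	No	MLH1:splice:5	141.6	1	0
LEC9_CAH	MLH1	-3	dMMR	N/A	None	0.8	0	1
LEC9_EEC	MLH1	0	dMMR	pLOH	None	14.5	1	1
LEC10_EEC	MLH1	0	dMMR	pLOH	None	29.1	1	0
LEC10_CxEC	MLH1	0	dMMR	pLOH	None	26.1	1	0
LEC11_CAH	MLH1	0	dMMR	pLOH	None	145.0	1	0
LEC11_EEC	MLH1	0	dMMR	No	MLH1:frameshift:14	68.1	1	0
LEC12_CAH	MLH1	0	dMMR	No	[MLH1:nonsense:3]	14.5	1	0
LEC12_EEC	MLH1	0	dMMR	No	[MLH1:nonsense:4]	23.1	1	0
LEC13_EEC	MSH2	0	dMMR	pLOH	None	9.2	0	1
LEC14_CAH	MLH1	0	pMMR	No	None	0.9	0	0
LEC14_EEC	MLH1	0	pMMR	No	None	9.5	0	0
LEC15_CCEC	MLH1	0	dMMR	No	MLH1:splice:20;MLH1:missense:19	13.6	1	1
LEC15_CAH	MLH1	0	dMMR	No	MLH1:splice:14	8.6	0	1
LEC16_EEC	MLH1	0	dMMR	LOH	None	36.9	1	1
LEC16_CAH	MLH1	0	dMMR	LOH	None	15.9	1	1
LEC17_CAH1	MLH1	-3	dMMR	No	MLH1:splice:7	4.7	0	0
LEC17_EEC	MLH1	0	dMMR	No	None	4.4	0	0
LEC17_CAH2	MLH1	0	dMMR	No	[MLH1:splice:4]	9.4	0	0
LEC19_EEC	MLH1	0	dMMR	No	MLH1:frameshift:28;MLH1:missense:12	173.1	1	0
LEC21_CAH	MLH1	0	dMMR	No	MLH1:frameshift:27	13.4	1	1
LEC21_EEC	MLH1	0	dMMR	No	MLH1:frameshift:35	12.8	1	1
LEC22_CAH	MSH2	0	dMMR	No	MSH2:missense:30	28.0	1	0
LEC22_EEC	MSH2	0	dMMR	No	MSH2:missense:29	31.3	1	0
LEC24_EEC	MLH1	0	dMMR	No	None	1.9	0	0
LOC1_CAH	MLH1	-3	dMMR	No	MLH1:frameshift:6;MLH1:frameshift:9	16.3	1	0
LOC1_EOC	MLH1	0	dMMR	No	MLH1:frameshift:5	16.4	1	0
LOC3_EEC	MLH1	0	dMMR	No	MLH1:frameshift:20	28.0	1	0
LOC3_CCOC	MLH1	0	dMMR	No	MLH1:frameshift:6	48.4	1	0
LOC4_EOC	MLH1	0	dMMR	No	MLH1:missense:35	45.2	1	0
LOC4_EEC	MLH1	0	dMMR	pLOH	None	203.0	1	0
LOC5_EOC	MSH2	0	dMMR	No	MSH2:nonsense:8	21.4	1	0
LOC5_CAH	MSH2	0	dMMR	No	MSH2:nonsense:6	10.0	1	0
LOC9_EOC	MLH1	0	dMMR	No	MLH1:nonsense:24	39.4	1	1
LOC9_EEC	MLH1	0	dMMR	No	MLH1:nonsense:21	34.5	1	1
LOC9_CAH	MLH1	0	dMMR	No	MLH1:nonsense:26	75.2	1	1
LOC12_CCOC	MLH1	0	dMMR	No	MLH1:nonsense:21	23.6	1	0
LOC12_CxEC	MLH1	0	dMMR	No	MLH1:nonsense:8	169.7	1	0
LOC13_EOC1	MLH1	0	dMMR	LOH	None	15.2	1	0
LOC13_EOC2	MLH1	0	dMMR	LOH	None	20.0	1	0
LOC13_CAH	MLH1	0	dMMR	LOH	None	144.1	1	0
LOC16_EOC	MLH1	0	dMMR	No	None	5.5	0	1
LOC16_EEC	MLH1	0	dMMR	No	MLH1:missense:16	67.8	1	1
LOC16_CAH	MLH1	0	dMMR	No	None	13.0	1	1
LOC17_EOC	MLH1	0	dMMR	No	MLH1:frameshift+splice:30	14.8	1	0
LOC18_EOC	MLH1	0	dMMR	LOH	None	12.5	1	0
LOC18_EEC	MLH1	0	dMMR	LOH	None	19.1	1	0
LOC18_CAH	MLH1	0	dMMR	LOH	None	98.0	1	0
LOC20_EOC	MSH2	0	dMMR	LOH	None	18.6	1	0
LOC21_CCOC	MLH1	0	dMMR	LOH	MLH1:missense:28	15.0	1	1
LOC22_CAH1	MLH1	-9	dMMR	No	MLH1:nonsense:44	14.1	1	0
LOC22_CAH2	MLH1	-7	dMMR	No	MLH1:nonsense:20	9.8	0	0
LOC22_CCOC1	MLH1	0	dMMR	No	MLH1:nonsense:6	13.8	1	0
LOC22_CCOC2	MLH1	0	dMMR	No	MLH1:nonsense:24	13.0	1	0
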