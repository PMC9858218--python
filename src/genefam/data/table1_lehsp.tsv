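subfamily	name	protein_id	exon	intron	loc_start	loc_end	chr	aa	mw_kda	pi
HSP100	LeHSP100.1	XP_046091847.1	9	8	6279738	6282864	1	890	98.436	5.48
HSP100	LeHSP100.2	XP_046082612.1	11	10	2522518	2526440	2	771	84.959	5.59
HSP100	LeHSP100.3	XP_046080071.1	11	10	3743879	3748058	6	749	83.108	5.54
HSP90	LeHSP90.1	XP_046088585.1	8	7	2407716	2410082	1	706	80.185	4.62
HSP90	LeHSP90.2	XP_046090891.1	19	18	1815650	1819056	5	817	91.712	4.29
HSP70	LeHSP70.1	XP_046088664.1	5	4	2657999	2660171	1	651	70.962	4.78
HSP70	LeHSP70.2	XP_046088714.1	9	8	2800610	2802917	1	613	67	5.24
HSP70	LeHSP70.3	XP_046086623.1	11	10	4172952	4175420	3	627	68.046	5.46
HSP70	LeHSP70.4	XP_046083696.1	9	8	1532467	1535557	8	886	97.597	5.52
HSP70	LeHSP70.5	XP_046079422.1	9	8	1824230	1826698	8	678	73.742	4.74
HSP70	LeHSP70.6	XP_046090274.1	4	3	288215	290346	10	631	66.324	4.41
HSP60	LeHSP60.1	XP_046082828.1	9	8	1726567	1728602	1	539	57.88	7.33
HSP60	LeHSP60.2	XP_046088531.1	8	7	2303108	2305148	1	554	59.722	6.24
HSP60	LeHSP60.3	XP_046092210.1	6	5	4944807	4946672	1	560	60.881	5.98
HSP60	LeHSP60.4	XP_046084390.1	9	8	1792382	1794487	4	550	59.833	6.63
HSP60	LeHSP60.5	XP_046084477.1	4	3	1298157	1300114	7	598	62.592	5.26
HSP60	LeHSP60.6	XP_046084950.1	8	7	1721053	1723408	7	575	62.377	5.79
HSP60	LeHSP60.7	XP_046088311.1	11	10	2236637	2238719	7	542	59.243	5.29
HSP60	LeHSP60.8	XP_046083662.1	8	7	1633717	1635690	8	561	60.138	5.91
HSP60	LeHSP60.9	XP_046079390.1	10	9	1750215	1752273	8	524	56.462	5.16
HSP40	LeHSP40.1	XP_046088819.1	6	5	3097898	3099296	1	398	43.547	6.44
HSP40	LeHSP40.2	XP_046091483.1	6	5	7116980	7118740	1	493	52.394	9.53
HSP40	LeHSP40.3	XP_046084554.1	11	10	1053764	1055625	7	422	46.417	4.59
HSP40	LeHSP40.4	XP_046084878.1	12	11	1936586	1938308	7	368	41.501	6.18
HSP40	LeHSP40.5	XP_046079519.1	4	3	2621252	2622535	7	372	39.857	9.66
HSP40	LeHSP40.6	XP_046082726.1	5	4	2888022	2889557	7	429	48.317	10.02
SHSP	LeSHSP.1	XP_046080632.1	4	3	3183573	3184343	2	190	21.261	10.33
SHSP	LeSHSP.2	XP_046088441.1	3	2	5037923	5037741	3	154	17.671	6.54
SHSP	LeSHSP.3	XP_046084164.1	2	1	1241615	1242240	4	188	20.37	4.83
SHSP	LeSHSP.4	XP_046088091.1	3	2	2943783	2944370	6	156	17.666	5.65
SHSP	LeSHSP.5	XP_046088092.1	3	2	2944818	2945400	6	155	17.409	5.45
SHSP	LeSHSP.6	XP_046082167.1	3	2	382364	382938	7	153	17.491	5.57
SHSP	LeSHSP.7	XP_046082168.1	4	3	383366	383941	7	162	18.492	6.45
SHSP	LeSHSP.8	XP_046080378.1	3	2	2094217	2095081	7	254	29.054	5.22
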