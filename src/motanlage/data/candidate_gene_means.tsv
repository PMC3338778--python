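gene	category	wt_mean	wt_sd	het_mean	het_sd	mut_mean	mut_sd	reported_fold
Acta1	actin	1449	107	1544	349	2486	230	1.8
Enah	actin	133	8	152	1	194	111	1.5
Actg2	actin	96	23	113	14	129	27	1.3
Palld	actin	294	21	352	23	376	113	1.3
Actn3	actin	1123	256	1017	88	650	17	-1.7
Csrp1	actin	819	174	820	52	526	94	-1.6
Ptpn11	actin	119	7	106	16	87	16	-1.4
Tpm3	actin	192	43	196	18	155	29	-1.2
Cap1	actin	1253	274	1257	293	1031	338	-1.2
Mapt	microtubule	44	3	51	13	256	144	5.8
Stmn2	microtubule	32	14	26	2	131	32	4.0
Stmn3	microtubule	71	2	62	21	236	106	3.3
Shroom3	microtubule	396	54	438	39	501	61	1.3
Tubb4	microtubule	130	56	141	84	165	29	1.3
Tubb3	microtubule	170	61	113	11	216	93	1.3
Tubb2b	microtubule	2216	312	2504	198	2766	426	1.2
Tubb5	microtubule	2079	91	1670	66	1460	45	-1.4
Dctn4	microtubule	129	13	122	31	94	45	-1.4
Myoz2	adhesion	189	11	211	35	319	69	1.7
Itga4	adhesion	1985	261	2180	427	2920	663	1.5
Adamts9	adhesion	169	92	167	32	239	63	1.4
Cyr61	adhesion	521	22	542	6	732	183	1.4
Fbln2	adhesion	372	167	357	23	467	16	1.4
Smoc1	adhesion	261	27	282	40	347	40	1.3
Spnb2	adhesion	123	1	147	11	162	67	1.3
Fat3	adhesion	441	55	466	8	578	72	1.3
Rnf165	adhesion	124	20	152	42	160	16	1.3
Sdc4	adhesion	188	15	200	5	127	29	-1.5
Sdc2	adhesion	360	42	404	61	251	37	-1.4
Adam19	adhesion	250	24	222	14	192	0	-1.3
Ctgf	adhesion	158	44	198	87	104	22	-1.3
Sgpp1	adhesion	169	43	145	6	128	33	-1.3
Jam3	adhesion	1258	137	1197	55	959	38	-1.3
Lmo7	adhesion	180	96	158	56	141	57	-1.3
Postn	adhesion	2110	186	1722	28	1625	77	-1.3
Tspan33	adhesion	367	133	375	30	300	23	-1.2
Prkar2b	signaling	118	9	137	58	185	15	1.6
Pdpk1	signaling	632	127	356	34	293	114	-2.2
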