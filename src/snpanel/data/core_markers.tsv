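marker	chrom	pos	ref	alt	pic	maf	gene_diversity	het_obs
CauSNP001	Chr1	860653	C	G	0.198	0.128	0.223	0.030
CauSNP002	Chr1	975765	C	T	0.359	0.375	0.469	0.386
CauSNP003	Chr1	1581568	C	A	0.351	0.350	0.455	0.316
CauSNP004	Chr1	2022083	A	T	0.372	0.442	0.493	0.568
CauSNP005	Chr1	2022902	C	T	0.357	0.366	0.464	0.733
CauSNP006	Chr1	9494597	G	T	0.348	0.340	0.449	0.450
CauSNP007	Chr1	16591554	A	C	0.304	0.249	0.374	0.359
CauSNP009	Chr1	45449565	T	A	0.367	0.410	0.484	0.401
CauSNP010	Chr2	3174530	A	G	0.375	0.497	0.500	0.532
CauSNP011	Chr2	14297682	G	A	0.374	0.474	0.499	0.541
CauSNP012	Chr2	39230790	T	A	0.365	0.401	0.481	0.486
CauSNP013	Chr2	65005201	C	T	0.375	0.485	0.500	0.416
CauSNP014	Chr2	66045832	A	T	0.349	0.344	0.451	0.389
CauSNP016	Chr3	6005226	T	C	0.372	0.447	0.494	0.407
CauSNP018	Chr3	73929470	T	C	0.220	0.147	0.251	0.155
CauSNP019	Chr3	75221240	C	T	0.262	0.192	0.310	0.128
CauSNP020	Chr4	14063327	C	G	0.374	0.465	0.498	0.499
CauSNP021	Chr4	52102326	G	A	0.365	0.403	0.481	0.410
CauSNP022	Chr5	311091	C	T	0.364	0.397	0.479	0.441
CauSNP023	Chr5	326763	G	C	0.363	0.392	0.477	0.420
CauSNP024	Chr5	4246754	G	C	0.345	0.331	0.443	0.334
CauSNP025	Chr5	42917099	G	C	0.372	0.448	0.495	0.568
CauSNP026	Chr5	42919228	T	C	0.371	0.438	0.492	0.565
CauSNP027	Chr6	1872141	G	A	0.373	0.454	0.496	0.538
CauSNP030	Chr6	34494441	G	C	0.364	0.398	0.479	0.468
CauSNP031	Chr6	40582776	G	T	0.372	0.448	0.495	0.562
CauSNP032	Chr6	46214109	C	T	0.371	0.436	0.492	0.410
CauSNP033	Chr7	6266029	G	A	0.373	0.459	0.497	0.492
CauSNP034	Chr7	7108476	T	G	0.288	0.225	0.349	0.006
CauSNP036	Chr7	18611643	C	G	0.372	0.445	0.494	0.021
CauSNP037	Chr7	26326101	G	A	0.274	0.207	0.328	0.000
CauSNP038	Chr7	49710841	C	T	0.353	0.356	0.458	0.383
CauSNP039	Chr8	685258	A	G	0.373	0.451	0.495	0.362
CauSNP040	Chr8	7993815	A	T	0.371	0.439	0.493	0.410
CauSNP041	Chr8	10333745	C	G	0.373	0.459	0.497	0.517
CauSNP042	Chr8	10995531	G	A	0.374	0.473	0.499	0.362
CauSNP044	Chr8	16285895	A	G	0.365	0.400	0.480	0.325
CauSNP045	Chr8	23662826	C	A	0.365	0.400	0.480	0.198
CauSNP046	Chr8	24753546	C	A	0.334	0.306	0.424	0.465
CauSNP047	Chr8	51980792	T	C	0.370	0.427	0.489	0.489
CauSNP048	Chr9	2367375	C	T	0.373	0.457	0.496	0.477
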