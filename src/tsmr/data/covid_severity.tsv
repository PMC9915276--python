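snp	chrom	pos	beta_exposure	se_exposure	pval_exposure	beta_outcome	se_outcome	pval_outcome
rs10850097	12	113361117	0.09552	0.01399	8.59e-12	-0.0001661	0.000145037	0.25
rs1120591	8	61537523	0.07600	0.01334	1.22e-8	-0.0000482	0.000143872	0.74
rs1123573	2	60707588	-0.12036	0.01438	5.64e-17	-0.0000551	0.000143234	0.70
rs1128175	6	31150435	-0.11827	0.01601	1.50e-13	-0.0001474	0.000166854	0.38
rs11614702	12	133058157	0.09967	0.01306	2.29e-14	-0.0001258	0.000138689	0.36
rs117169628	16	89264460	0.14967	0.01965	2.60e-14	0.0001962	0.000183068	0.28
rs12585036	13	113535741	0.14326	0.01609	5.28e-19	0.0001735	0.000170713	0.31
rs12610495	19	4717672	0.24613	0.01530	3.28e-58	-0.0001029	0.000151855	0.50
rs12614007	2	57316503	0.08889	0.01604	2.99e-8	-0.0001245	0.000162446	0.44
rs2070788	21	42841988	-0.07615	0.01336	1.19e-8	-0.0000560	0.000140635	0.69
rs2897075	7	99630342	0.07714	0.01334	7.30e-9	0.0000651	0.000143991	0.65
rs2924480	11	34529831	-0.13204	0.01445	6.52e-10	0.0001407	0.000146439	0.34
rs2983793	10	81445802	0.08640	0.01421	1.18e-9	-0.0000194	0.000146350	0.89
rs34712979	4	106819053	-0.11042	0.01712	1.13e-10	0.0000806	0.000159248	0.61
rs35617599	19	50874794	0.09594	0.01398	6.77e-12	0.0002727	0.000148087	0.07
rs550057	9	136146597	0.11508	0.01501	1.73e-14	-0.0000480	0.000159173	0.76
rs646327	19	49209851	-0.09538	0.01338	1.00e-12	0.0003092	0.000139088	0.03
rs7528403	1	65382792	-0.09740	0.01686	7.58e-9	0.0000079	0.000179455	0.96
rs7664615	4	25448493	-0.09472	0.01697	2.40e-8	0.0002145	0.000184190	0.24
rs9636867	21	34609944	0.18972	0.01387	1.32e-42	-0.0001185	0.000150267	0.43
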