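snp	chrom	pos	beta_exposure	se_exposure	pval_exposure	beta_outcome	se_outcome	pval_outcome
rs10774679	12	113374748	0.08358	0.00950	1.36e-18	-0.0001198	0.000143988	0.41
rs11208552	1	65412830	-0.05736	0.00989	6.70e-9	-0.0000870	0.000152264	0.57
rs1123573	2	60707588	-0.08188	0.01016	7.45e-16	-0.0000551	0.000143234	0.70
rs117169628	16	89264460	0.10477	0.01391	5.09e-14	0.0001962	0.000183068	0.28
rs11790730	9	33425871	0.07587	0.01218	4.68e-10	0.0001500	0.000170557	0.38
rs12151726	2	198273591	0.05732	0.00975	4.11e-9	-0.0001513	0.000139912	0.28
rs12585036	13	113535741	0.10643	0.01108	7.75e-22	0.0001735	0.000170713	0.31
rs12610495	19	4717672	0.16432	0.01075	9.89e-53	-0.0001029	0.000151855	0.50
rs17412601	3	101499275	-0.06815	0.00978	3.24e-12	-0.0000153	0.000145432	0.92
rs2068205	6	33058583	0.05430	0.00965	1.83e-8	0.0000754	0.000140680	0.59
rs2897075	7	99630342	0.05229	0.00929	1.82e-8	0.0000651	0.000143991	0.65
rs34712979	4	106819053	-0.07190	0.01214	3.21e-9	0.0000806	0.000159248	0.61
rs383510	21	42858367	-0.05397	0.00946	1.14e-8	-0.0001404	0.000139530	0.31
rs4403445	8	61432007	0.05845	0.00903	9.82e-11	-0.0000500	0.000143867	0.73
rs5023077	12	133141973	-0.06962	0.00911	2.11e-14	0.0001197	0.000138878	0.39
rs550057	9	136146597	0.09880	0.01030	8.74e-22	-0.0000480	0.000159173	0.76
rs55938136	17	43798360	-0.08588	0.01524	1.73e-8	-0.0001077	0.000166166	0.52
rs638294	19	50863023	0.08651	0.00945	5.67e-20	0.0002897	0.000148130	0.05
rs646327	19	49209851	-0.06890	0.00933	1.54e-13	0.0003092	0.000139088	0.026
rs717624	7	22894487	-0.05379	0.00947	1.34e-8	-0.0000330	0.000140778	0.81
rs7515509	1	77949123	0.05838	0.00966	1.52e-9	0.0000306	0.000142052	0.83
rs7671107	4	25449225	-0.07412	0.01099	1.51e-11	0.0001520	0.000170930	0.37
rs7949972	11	34502042	-0.09310	0.00919	3.94e-24	0.0000298	0.000143289	0.84
rs9636867	21	34609944	0.14045	0.00940	1.83e-50	-0.0001185	0.000150267	0.43
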