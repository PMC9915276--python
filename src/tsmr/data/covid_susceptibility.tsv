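snp	chrom	pos	beta_exposure	se_exposure	pval_exposure	beta_outcome	se_outcome	pval_outcome
rs10774675	12	113361237	0.03373	0.00476	1.38e-12	-0.0001386	0.000144861	0.34
rs1123573	2	60707588	-0.02794	0.00465	1.83e-9	-0.0000551	0.000143234	0.70
rs12610495	19	4717672	0.05967	0.00509	1.02e-30	-0.0001029	0.000151855	0.50
rs12972221	19	50879140	0.02932	0.00467	3.30e-10	0.0002772	0.000148189	0.06
rs17860169	21	34613301	0.04196	0.00461	8.90e-20	-0.0001103	0.000150124	0.46
rs2260685	3	195497743	0.02716	0.00455	2.33e-9	0.0000559	0.000139376	0.69
rs2290859	3	101525625	-0.05132	0.00473	1.79e-27	-0.0000054	0.000145542	0.97
rs505922	9	136149229	0.08592	0.00449	1.05e-81	-0.0001457	0.000148905	0.33
rs721917	10	81706324	0.02802	0.00437	1.48e-10	0.0002773	0.000140657	0.05
rs78295726	19	10426512	0.03438	0.00629	4.60e-8	0.0000290	0.000182971	0.87
rs7949972	11	34502042	-0.02867	0.00450	1.87e-10	0.0000298	0.000143289	0.84
rs914615	1	155175892	-0.02480	0.00437	1.38e-8	-0.0000145	0.000138969	0.92
rs9916158	17	38182229	0.02569	0.00449	1.10e-8	0.0002619	0.000143728	0.07
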