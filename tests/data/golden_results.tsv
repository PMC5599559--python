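snp_names	k	G	df	p_value	excluded_genotypes	significant	threshold
SNP13,SNP16	2	88.13603329	7	2.985397071e-16	2-2	true	0.0002631578947
SNP4,SNP13	2	32.54482367	4	1.480247439e-06	1-2;2-0;2-1	true	0.0002631578947
SNP6,SNP13	2	42.36464314	4	1.401656597e-08	1-2;2-1;2-2	true	0.0002631578947
SNP2,SNP13	2	42.81463933	5	4.028910446e-08	2-0;2-1;2-2	true	0.0002631578947
SNP10,SNP13	2	44.45450035	7	1.744913938e-07	2-2	true	0.0002631578947
SNP8,SNP13	2	40.57495926	5	1.143309296e-07	2-0;2-1;2-2	true	0.0002631578947
SNP12,SNP13	2	33.30773678	6	9.148668479e-06	0-2;2-2	true	0.0002631578947
SNP5,SNP13	2	41.77944031	5	6.527830456e-08	2-0;2-1;2-2	true	0.0002631578947
SNP3,SNP13	2	35.9102194	7	7.53760755e-06	2-2	true	0.0002631578947
SNP2,SNP6	2	4.297230323	4	0.3672720457	0-2;1-2	false	0.0002631578947
SNP4,SNP6	2	4.040409313	3	0.2571335853	0-2;1-2;2-0;2-1	false	0.0002631578947
SNP0,SNP6	2	3.086590721	3	0.3784663169	0-2;1-2;2-0;2-1	false	0.0002631578947
SNP5,SNP6	2	3.200438684	4	0.5248600947	0-2;1-2;2-1	false	0.0002631578947
SNP0,SNP4	2	0.5105423633	3	0.9165692705	0-2;1-2;2-0;2-2	false	0.0002631578947
SNP6,SNP14	2	4.595358216	4	0.3313897223	1-2;2-0;2-1	false	0.0002631578947
SNP0,SNP2	2	2.260886374	4	0.6878990648	1-2;2-1	false	0.0002631578947
SNP0,SNP5	2	1.296882675	4	0.8619042099	1-2;2-0;2-1	false	0.0002631578947
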