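snp_names	k	k2	gini	entropy
SNP13,SNP16	2	388.1758942	0.428906715	2.819281451
SNP4,SNP13	2	406.3694953	0.4632830679	2.226086685
SNP6,SNP13	2	406.5352198	0.464783619	2.117996914
SNP2,SNP13	2	408.1995701	0.4644966965	2.463612323
SNP10,SNP13	2	408.3340674	0.4619632061	2.774658851
SNP8,SNP13	2	408.4093506	0.4632218552	2.592915194
SNP12,SNP13	2	408.6636865	0.4624573785	2.802059229
SNP5,SNP13	2	408.6662466	0.4643614399	2.526529349
SNP3,SNP13	2	408.9000924	0.4634694467	2.770727733
SNP2,SNP6	2	422.8223532	0.4930971979	1.761004536
SNP4,SNP6	2	422.9502489	0.493783355	1.533916355
SNP0,SNP6	2	423.3846556	0.4954999902	1.440907519
SNP5,SNP6	2	424.0353764	0.4948444887	1.827719979
SNP0,SNP4	2	424.4459942	0.4962418279	1.536142622
SNP6,SNP14	2	424.5412258	0.4956603376	1.840024543
SNP0,SNP2	2	425.4958565	0.4979530525	1.769800678
SNP0,SNP5	2	425.6292781	0.4972539581	1.840414282
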