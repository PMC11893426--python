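exposure	mediator	outcome	total_b	total_se	a_b	a_se	b_b	b_se	med_b	med_se	med_p	prop_pct	prop_lo	prop_hi	label
CXCL6	Androstenediol (3beta,17beta) monosulfate (2) levels	Male infertility	1.1979	0.3238	-0.0787	0.0321	-0.2124	0.1002	0.0167	0.0109	0.1253	1.4	-0.39	3.18	mediation
CXCL6	Sphingomyelin (d18:1/20:2, d18:2/20:1, d16:1/22:2) levels	Male infertility	1.1979	0.3238	0.0640	0.0302	-0.1803	0.0899	-0.0115	0.0084	0.1684	-0.96	-2.33	0.41	suppression
CXCL6	Sphingomyelin (d18:1/20:1, d18:2/20:0) levels	Male infertility	1.1979	0.3238	0.0724	0.0305	-0.1873	0.0947	-0.0136	0.0094	0.1483	-1.13	-2.67	0.4	suppression
CXCL6	Arachidonoylcholine levels	Male infertility	1.1979	0.3238	0.0646	0.0329	0.2228	0.1121	0.0144	0.0109	0.1885	1.2	-0.59	2.99	mediation
CXCL6	X-12822 levels	Male infertility	1.1979	0.3238	-0.0847	0.0328	0.2171	0.1066	-0.0184	0.0120	0.1262	-1.53	-3.5	0.43	suppression
CXCL6	Phosphate to glycerol ratio	Male infertility	1.1979	0.3238	-0.0644	0.0302	-0.3449	0.1549	0.0222	0.0152	0.1432	1.85	-0.63	4.33	mediation
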