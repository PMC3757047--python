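chrom	name	start	end	family	strand	trna	tsd	completeness	note
I	Ty_YAR023C-UIP3	180826	180845	Ty1	-	yes	GTTTA	full	span inconsistent with two-coordinate insertion-site convention; stored verbatim
II	Ty_YBL108W-YBL107C	9462	9463	Ty1	+	yes	N.D.	full	subtelomeric; inserted in a novel SK1 LTR; carrying chromosome end uncertain
III	Ty_TEL03L-YCL073C	1180	4322	Ty5	+	no	N.D.	full	subtelomeric; same element as YCLWTy5-1 in S288C
III	Ty_SRD1-MAK32	151729	151730	Ty2	-	yes	GAATC	full
III	Ty_RIM1-SYP1	173740	173741	Ty1	-	no	AAATC	full
IV	Ty_EXG2-YDR262W-1	992677	992678	Ty1	+	yes	AAGAT	full	adjacent to Ty_EXG2-YDR262W-2, inverted orientation
IV	Ty_EXG2-YDR262W-2	992677	992678	ambiguous	-	yes	N.D.	fragment	>1 kb fragment adjacent to Ty_EXG2-YDR262W-1
IV	Ty_OMS1-HIM1	1095501	1095502	Ty1	-	yes	ATATG	fragment	~1 kb fragment
IV	Ty_FCF1-YDR341C	1151116	1151117	Ty1	+	yes	GTCTA	full	inserted in a novel SK1 LTR
V	Ty_UTR2-CYC7	79534	79535	Ty2	-	no	AATAT	full
V	Ty_URA3	116283	116284	Ty1	+	no	CGTAC	full	family assigned externally (Gabriel et al. 2006)
V	Ty_YER137C-RTR1	449646	449647	Ty1	+	yes	N.D.	full	family assigned externally (Gabriel et al. 2006); inserted in a novel SK1 LTR
VI	Ty_MSH4-SPB4	137731	137732	Ty1	+	yes	N.D.	full
VII	Ty_YGL226W-VRG4	74930	74931	Ty2	+	yes	GATAA	full
VII	Ty_CGR1-SCW11	441007	441008	Ty1	-	yes	ATAAT	full
VII	Ty_ERV1-POP6	544849	544850	Ty1	-	yes	AATAT	full
VII	Ty_YGR150C-RSR1	794408	794409	Ty1	+	yes	ATATT	full	inserted in a novel SK1 LTR
IX	Ty_EST3-FAA3	336955	336956	Ty1	-	yes	GTTTT	full
X	Ty_ASF1-MDV1	204645	204646	Ty1	+	yes	AAAGG	full
XI	Ty_STB6-YKL071W	301921	301922	Ty1	+	yes	GAAGG	full
XI	Ty_SIS2-YKR074W	578126	578127	Ty1	-	yes	ATTAG	full
XII	Ty_MID2-RPS25B	793754	793755	Ty2	+	yes	ACTAT	full
XIII	Ty_YMR118C-ASI1	504714	504715	Ty1	-	yes	ATTAT	full	inserted in a novel SK1 LTR
XIV	Ty_CUS2-MRPL10	96517	96521	Ty1	-	yes	TATAT	full	inserted in a novel SK1 LTR; LTR insertion-site span stored verbatim
XIV	Ty_NCE103-YNL035C-1	560747	560748	Ty2	+	yes	GAAAC	full	disrupted by Ty_NCE103-YNL035C-2
XIV	Ty_NCE103-YNL035C-2	560747	560748	ambiguous	-	yes	N.D.	full	inserted into Ty_NCE103-YNL035C-1, inverted orientation
XIV	Ty_YNL035C-YNL034W	569954	569955	Ty3	-	yes	GTTTT	full
XVI	Ty_PEX25-CAR1	339200	339402	Ty1	-	yes	-	full	target-site duplication not observed
XVI	Ty_CLB5-THI22	776100	776101	Ty1	+	yes	ATGAA	full
XVI	Ty_KRE6-GPH1	859975	859976	Ty1	+	yes	GTTTA	full
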