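gene_name	accession	chromosome	start	end	strand	protein_length	subgenome	paralog_partner
ZmIAA1	GRMZM2G079957_T2	1	170535129	170536982	1	227	1	ZmIAA8
ZmIAA2	GRMZM2G159285_T1	1	275031309	275034076	-1	237	1	ZmIAA14
ZmIAA3	GRMZM5G809195_T1	1	288394822	288396335	-1	202	1	ZmIAA13
ZmIAA4	GRMZM2G104176_T1	3	7117449	7120087	-1	229	1
ZmIAA5	GRMZM2G004696_T1	3	10073330	10076684	1	220	1	ZmIAA27
ZmIAA6	GRMZM2G074742_T1	3	48981283	48983063	1	198	1
ZmIAA7	GRMZM2G138268_T1	3	117766041	117770646	-1	271	2
ZmIAA8	GRMZM2G167794_T1	3	118064610	118066326	-1	230	2	ZmIAA1
ZmIAA9	GRMZM2G057067_T1	3	199305498	199307986	-1	357	1
ZmIAA10	GRMZM2G037368_T1	3	209094740	209098102	-1	269	1	ZmIAA29
ZmIAA11	GRMZM2G059544_T2	4	39557305	39558529	-1	251	2
ZmIAA12	GRMZM2G142768_T1	4	171373109	171375531	1	293	2
ZmIAA13	GRMZM2G152796_T1	5	4200507	4201934	-1	181	2	ZmIAA3
ZmIAA14	GRMZM2G077356_T1	5	7772505	7775451	1	228	2	ZmIAA2
ZmIAA15	GRMZM2G128421_T1	5	17343149	17344582	1	224	unassigned
ZmIAA16	GRMZM2G121309_T1	5	151712395	151716302	1	289	1
ZmIAA17	GRMZM2G030465_T1	5	214411995	214413229	1	206	1
ZmIAA18	GRMZM2G000158_T4	6	79914748	79916495	-1	197	2	ZmIAA30
ZmIAA19	GRMZM2G079200_T1	6	103139630	103141327	-1	198	2
ZmIAA20	GRMZM5G864847_T1	6	130004758	130006167	-1	234	unassigned
ZmIAA21	GRMZM2G147243_T2	6	133196856	133200588	1	244	1	ZmIAA28
ZmIAA22	GRMZM2G141205_T1	6	146505719	146506414	-1	231	unassigned
ZmIAA23	GRMZM2G074427_T2	6	160166708	160170208	1	346	1
ZmIAA24	GRMZM2G149449_T1	7	9392913	9393634	1	115	unassigned
ZmIAA25	GRMZM2G115357_T2	7	10970395	10971721	-1	66	1
ZmIAA26	GRMZM2G048131_T1	7	142773908	142775365	1	139	1
ZmIAA27	GRMZM2G130953_T2	8	18318828	18320919	-1	186	2	ZmIAA5
ZmIAA28	GRMZM2G035465_T3	8	110812538	110816166	-1	256	2	ZmIAA21
ZmIAA29	GRMZM2G163848_T5	8	150560417	150563479	1	272	2	ZmIAA10
ZmIAA30	GRMZM2G001799_T1	9	16249556	16251444	1	216	1	ZmIAA18
ZmIAA31	GRMZM2G134517_T1	10	134255159	134255926	-1	255	unassigned
ZmIAA32	GRMZM2G366373_T2	1	253302210	253303545	-1	226	unassigned
ZmIAA33	GRMZM2G359924_T1	8	108568427	108570670	1	228	unassigned
ZmIAA34	GRMZM2G031615_T2	4	16418192	16426336	1	355	1
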