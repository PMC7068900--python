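inversion	chrom	start	end	size	micro	caller	validation
1paa	1	3662097	3696373	34276	1	Long Ranger	Assembly
1pab	1	12833450	12864379	30929	1	Long Ranger	Long-read align
1pa	1	28526219	110482104	81955885	0	GROC-SVs	Long-read align
1cb	1	86573078	207047458	120474380	0	Long Ranger	Long-read align
1pac	1	110426504	110463452	36948	1	Long Ranger	Assembly
1qad	1	151766620	151847533	80913	1	Both	Long-read align
1qae	1	258805045	258838552	33507	1	GROC-SVs	Long-read align
1qaf	1	261838607	261877216	38609	1	Long Ranger	Assembly
1qag	1	273812946	273859121	46175	1	GROC-SVs	Long-read align
1qah	1	288864540	288902671	38131	1	Long Ranger	Both
2pc	2	36263327	68515898	32252571	0	Both	Long-read align
2pai	2	125768796	125807158	38362	1	Long Ranger	Long-read align
2pd	2	178843909	215734436	36890527	0	GROC-SVs	Long-read align
2qe	2	242868946	392168275	149299329	0	GROC-SVs	Long-read align
2qaj	2	276157193	276249519	92326	1	Long Ranger	Long-read align
2qak	2	312677653	312836936	159283	1	Both	Long-read align
2qal	2	387870950	387930807	59857	1	Long Ranger	Long-read align
2qam	2	456306790	456341898	35108	1	Long Ranger	Both
3pf	3	30056138	138778486	108722348	0	GROC-SVs	Long-read align
3pan	3	43852147	43896847	44700	1	Long Ranger	Long-read align
3pao	3	61571542	61611075	39533	1	Long Ranger	Long-read align
3pap	3	72073163	72216512	143349	1	Long Ranger	Long-read align
3paq	3	83753676	83794150	40474	1	Long Ranger	Long-read align
3cg	3	119518403	392983952	273465549	0	Both	Long-read align
3ph	3	161230873	171356784	10125911	0	Both	Long-read align
3qi	3	196536178	280271694	83735516	0	GROC-SVs	Long-read align
3qar	3	198751700	198836215	84515	1	Long Ranger	Long-read align
3qas	3	213245322	213670971	425649	1	Long Ranger	Long-read align
3qat	3	229688967	229782178	93211	1	Long Ranger	Both
3qau	3	257058020	257252866	194846	1	Both	Both
3qav	3	374671141	374714093	42952	1	Long Ranger	Assembly
3qaw	3	386773996	386844766	70770	1	Long Ranger	Long-read align
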